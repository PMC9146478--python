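# Methods

This note documents the models, numerical choices and limitations of the
`vagdx` pipeline, stage by stage.

## Synthetic cohort

The clinical recordings this protocol targets are not publicly available,
so the package ships a generative model of the *signal morphology* the
pipeline must handle — not of cartilage physics. One recording couples:

* an **encoder channel** (10 Hz, hard-stopped to [0°, 90°]): per cycle a
  piecewise cosine 90→0→90 over ~2 s with uniform per-cycle duration
  jitter (±10 %), idle padding (1 s at 90°) before and after motion, and
  0.1° measurement noise;
* an **acoustic channel** (1400 Hz, quantized to 10 bits over full scale
  [−1, 1]) summing five sources, all in relative full-scale units:
  * broadband background noise (white, low-passed at 600 Hz; std 0.04),
  * a **friction term**: 50–250 Hz band noise whose envelope tracks
    |dθ/dt|, scaled by a kinetic-chain loading profile — open chain loads
    the extension phase (gain 1.0 vs 0.35), closed chain loads both phases
    (gain 0.75), reflecting seated extension vs sit-to-stand mechanics;
  * **lesion bursts**: Poisson-placed exponentially damped sinusoids
    (carrier 50–400 Hz, decay 10–30 ms), with rate (0.5, 2, 4, 6, 8 per
    cycle) and amplitude (0.04, 0.10, 0.22, 0.38, 0.55) indexed by ICRS
    grade 0–4 — the monotone severity→burst-energy map is the signal the
    classifiers must find;
  * **sensor drift**: integrated low-pass noise — a slope process
    smoothed on a 24 s scale (longer than one recording) and then
    integrated — scaled to peak amplitude 0.25. By construction every
    realization is trend-like (monotone or single-turn) over a recording
    and therefore lands in the EMD residual, which is what the detrending
    stage removes;
  * 50 Hz mains hum (amplitude 0.01).

Demographics are sampled per group from normal distributions matching the
target cohort (HC: age 24.1 ± 5.6 y, height 1.71 ± 0.09 m, weight
65.2 ± 15.1 kg; OA: 56.2 ± 13.0 y, 1.69 ± 0.09 m, 89.1 ± 14.3 kg; BMI
derived; sex ratios 9/24 and 15/19 M/F). Controls contribute both knees
(`knees_per_hc = 2`), OA subjects the operated knee, reproducing the
66-vs-34 case structure. Default OA grades are {2, 3, 4}, the
moderate-to-severe lesions the protocol's validation cohort represents;
grade 1 is available through configuration. Sex carries no acoustic
effect — it is a covariate only.

What the generator does **not** emulate: real VAG spectra, muscle-artifact
nonstationarity, inter-session sensor placement variability, or any
overlap-inducing confounding between demographics and disease (age and BMI
separate the groups strongly, as they do in the target cohort). Passing
end-to-end tests therefore demonstrates that the pipeline's machinery is
correct and discriminates when grade-dependent structure exists — not that
the protocol reaches any particular accuracy on clinical data.

## Preprocessing

Stage order: cycle cutting → EEMD → residual removal → [0, 1]
normalization.

**Cycle detection.** A full cycle is a descent from ≥85° to ≤5° and a
return to ≥85°. Threshold-crossing anchors are refined by walking to the
adjacent slope break (where the backward/forward step falls below 0.5°,
above the 0.1° encoder noise), landing boundaries on the hard-stop plateau
edge; detected boundaries sit within one encoder period (0.1 s) of the
generator's ground truth. A trace whose largest step is below 2° per
encoder period is motionless → empty result (error at the pipeline level).
Adjacent cycles may share a boundary sample; segments are half-open.

**EMD.** Envelopes are cubic splines through the local extrema, with the
two outermost extrema mirrored across each boundary to tame end swings
(natural boundary conditions when fewer than four knots). A proto-IMF is
accepted when *both* the Cauchy criterion SD = Σ(d_prev−d)²/Σd_prev² < 0.2
*and* the extrema/zero-crossing admissibility condition
(|#extrema − #zero-crossings| ≤ 1) hold, with a hard cap of 10 sifts per
IMF (a warning is logged if the cap preempts admissibility). The SD stop
alone routinely leaves inadmissible modes on broadband noise. Decomposition
stops when the remainder has fewer than two maxima or minima, when it is
numerically monotone — the proto-IMF's std below 0.2× the remainder's, the
tolerance on the "remainder is a trend" condition; genuine modes measure
≥ 0.5 on every fixture while pseudo-modes carved out of a trend by
sparse-extrema envelopes measure ≤ 0.1 — or at ⌊log₂ n⌋ IMFs. The identity Σ IMFs + residual = x telescopes exactly
(≤1e-9 relative, in practice machine precision).

**EEMD.** Each of N trials decomposes x + wₙ with wₙ white Gaussian of std
0.2·std(x) (the 0.2 is interpreted as relative, the common convention;
plain EEMD, not the paired-noise CEEMD variant). Trials are seeded
`default_rng([seed, trial])`. IMF lists of differing depth are aligned by
zero-padding to the deepest before averaging. The ensemble mean
reconstructs x + mean(wₙ), so the reconstruction error shrinks as
0.2·std(x)/√N — verified at N ∈ {1, 16, 100}. The protocol default is
N = 100; the end-to-end experiments in the tests, the acceptance script
and the analysis scripts use N = 16, the package's chosen problem size for
a single-workstation run (the √N error floor at N = 16 is ~5 % of signal
std and does not limit classification).

**Detrending** subtracts only the ensemble-mean residual r(t). On a
drifted recording this recovers the drift-free signal (correlation > 0.97
with a paired drift-free twin) while plain-EMD detrending of a linear
drift removes >99.9 % of sub-1 Hz energy.

**Normalization** maps to [0, 1]; constant signals are an error, not a
silent degenerate output.

## Feature extraction

Features are computed per recording on the concatenated cleaned cycles
(a per-cycle averaging mode exists), matching one-case-per-recording
bookkeeping. Conventions follow the classical condition-monitoring
definitions: VAR uses the unbiased 1/(N−1) estimator; KUR, M6A, M8A use
biased 1/N central moments in numerator and denominator; SF is RMS/SA
(on the non-negative normalized signals SA ≡ MV, making the two published
notations coincide). Ratio measures with vanishing denominators raise —
on [0, 1]-normalized physiological signals those states are unreachable,
so reaching one flags an upstream bug. Scale invariances and the moment
ordering M8A ≥ M6A ≥ KUR ≥ 1 (power-mean inequality) are property-tested;
every measure is checked against a direct-summation oracle at 1e-12.

## NCA feature selection

The feature-selection variant of NCA: weighted-L1 distance with squared
weights, kernel κ(z) = exp(−z/σ) (read as −z/σ so that larger σ means a
wider kernel; the alternative −z·σ is the reparameterization σ → 1/σ),
leave-one-out soft-NN accuracy, L2 penalty λ. The gradient is derived
analytically from the objective (the published closed form for this
gradient is typographically corrupted) and validated against central
finite differences at 1e-5. Leave-one-out probabilities are computed as a
row softmax of −D/σ with an off-diagonal row-min shift for underflow
safety.

Numerical choices: features standardized (training folds only — the
inputs mix years, kg/m² and dimensionless moments); σ = 1
post-standardization; λ tuned on a 10-point log grid [1e-4, 1]/N by
stratified 5-fold CV (stratification guarantees both classes in every
fold of a 2-class problem); optimizer is gradient ascent from w = 1 with
backtracking line search (Armijo condition, max 400 iterations, 1e-6
relative tolerance) so the objective never decreases along accepted
steps. Features with wₗ² ≥ 0.05·max wₗ² are retained. NCA weights only
the 12 signal measures; the demographic covariates are always classifier
inputs.

## Classification

**Split**: stratified 70/15/15 train/test/validation by seeded per-class
shuffling (rounded per class, remainder to validation).

**MLP**: one hidden layer; hidden activations linear/logistic/tanh/
exponential/gauss; output softmax (or exponential/linear); loss
cross-entropy (softmax only) or sum-of-squares; Glorot-uniform seeded
init; trained by L-BFGS capped at the configured iteration count, retaining
the iterate with the lowest validation classification error. For
probability output, exponential activations are normalized (identical to
softmax of the pre-activations); linear outputs are shifted and
normalized.

**RBF**: k-means centers on standardized inputs (centers = training
points when n_hidden = n_train); per-center width = mean distance to the
2 nearest other centers (floored at 1e-6, times an optional width scale);
Gaussian units exp(−‖x−c‖²/2σ_c²); output layer fit as a convex softmax
cross-entropy problem (1e-8 ridge for conditioning only).

**Model search** trains a small documented grid per family and ranks by
validation accuracy; because a 15-case validation split saturates (many
candidates at 100 %), ties are broken by the mean validation true-class
probability — a continuous confidence margin — then by name. The
leaderboard mirrors the published table format ("MLP 9-40-2", learning/
testing/validation accuracy, algorithm, error and activation functions).
Published iterate counts such as "BFGS 17" are treated as iteration caps.

**Variants**: I = OKC, II = CKC (following the published results tables
where the running text is self-contradictory), III = both chains stacked
as separate observations with a 0/1 chain-indicator input (forced by the
published variant-III case totals, 136 = 68×2).

## Evaluation

OA is the positive class. Accuracy, per-group correct percentages,
sensitivity/specificity/precision (both orientations — published summary
tables for this protocol mix them; F1 and MCC are orientation-anchoring),
F1, MCC; ROC by threshold sweep over unique scores from (0,0) to (1,1);
trapezoidal AUC (equal to Mann–Whitney concordance with ties at ½); the
reported operating threshold maximizes Youden's J, ties toward the larger
threshold. Metrics with zero denominators are flagged undefined rather
than substituted.

**Label-permutation control.** The chance-level control retrains the
reference MLP on permuted labels. Because controls contribute two knees,
the cohort prior is 66:34 and plain accuracy has its chance level at the
majority share (~66 %); the control therefore scores *balanced* accuracy
(mean of per-class accuracies), whose chance level is 50 % under any
prior, averaged over 5 permutation replicates as permutation tests
conventionally do. The informative-label pipeline is still scored with
plain accuracy.

## Determinism

One master seed fans out to per-stage sub-seeds via
`SeedSequence([master, stage_code, index])` (cohort = 1, EEMD = 2 with the
recording index, NCA = 3, split = 4, MLP = 5, RBF = 6, permutation = 7).
Reruns of a variant reproduce every artifact byte-for-byte.

## Known limitations

* The EEMD ensemble-mean residual carries an averaging error that shrinks
  only as 1/√N; small ensembles leave visible low-frequency remnants.
* The RBF recipe (k-means + convex output fit) is one standard reading of
  the "RBFT" trainer named in the published tables, whose internals are
  undocumented; the published input counts per variant also cannot be
  itemized exactly, so network shapes are derived from the data, not
  forced to match.
* Published real-cohort accuracies are not reproducible without the
  clinical data; the synthetic cohort is the acceptance surface, and the
  only published numbers asserted exactly are those derivable from the
  printed confusion counts.
* ROC curves are computed on the 15-case test split; AUC on so few points
  is coarse.
* The impulse-sensitive signal measures (VAR, KUR, M6A, M8A) are strongly
  correlated, and NCA's weighting — like any L1-style criterion — sometimes
  concentrates the entire weight mass on one of them (roughly 2 in 10
  cohort draws). When only a single signal measure survives selection, a
  control subject with atypical covariates (an older, high-BMI volunteer)
  can fall inside the OA region of the reduced input space and cost one
  test case (93.3 % instead of 100 %) for both network families; with two
  or more signal measures selected, the held-out split is classified
  perfectly in every cohort draw examined.
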