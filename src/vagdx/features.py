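"""Time-domain signal measures and per-case input assembly.

Twelve classical condition-monitoring statistics computed on the cleaned,
[0,1]-normalized signal: mean (MV), straightened average (SA, mean of |x|),
RMS, peak value (PV, max |x|), peak-to-peak (PPV), crest factor (CF=PV/RMS),
impact factor (IF=PV/MV), shape factor (SF=RMS/SA), unbiased variance (VAR,
1/(N-1)), and the normalized even central moments: kurtosis (KUR, 4th/var^2),
M6A (6th/var^3) and M8A (8th/var^4) — the higher moments use the biased 1/N
convention in both numerator and denominator and grow with signal
impulsiveness, which is what cartilage-lesion clicks produce.

Ratio measures with a vanishing denominator raise FeatureUndefinedError
rather than returning a sentinel: on normalized physiological signals these
states are unreachable, so hitting one signals an upstream bug.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import Chain, Group, SubjectProfile

FEATURE_NAMES = ["mv", "sa", "rms", "pv", "ppv", "cf", "if_", "sf",
                 "var", "kur", "m6a", "m8a"]

#: measures invariant under positive rescaling of the signal
SCALE_INVARIANT = ["cf", "if_", "sf", "kur", "m6a", "m8a"]


class FeatureUndefinedError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureVector:
    mv: float
    sa: float
    rms: float
    pv: float
    ppv: float
    cf: float
    if_: float
    sf: float
    var: float
    kur: float
    m6a: float
    m8a: float
    n_samples: int

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in FEATURE_NAMES])


def extract_features(x: np.ndarray) -> FeatureVector:
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    mv = float(np.mean(x))
    sa = float(np.mean(np.abs(x)))
    rms = float(np.sqrt(np.mean(x**2)))
    pv = float(np.max(np.abs(x)))
    ppv = float(abs(x.max() - x.min()))
    if rms == 0:
        raise FeatureUndefinedError("CF undefined: rms = 0")
    cf = pv / rms
    if mv == 0:
        raise FeatureUndefinedError("IF undefined: mean = 0")
    if_ = pv / mv
    if sa == 0:
        raise FeatureUndefinedError("SF undefined: straightened average = 0")
    sf = rms / sa
    d = x - mv
    var = float(np.sum(d**2) / (n - 1))
    m2 = float(np.mean(d**2))
    if m2 == 0:
        raise FeatureUndefinedError("KUR/M6A/M8A undefined: zero variance")
    kur = float(np.mean(d**4)) / m2**2
    m6a = float(np.mean(d**6)) / m2**3
    m8a = float(np.mean(d**8)) / m2**4
    return FeatureVector(mv=mv, sa=sa, rms=rms, pv=pv, ppv=ppv, cf=cf, if_=if_,
                         sf=sf, var=var, kur=kur, m6a=m6a, m8a=m8a, n_samples=n)


def extract_features_per_cycle(cycles: list[np.ndarray]) -> FeatureVector:
    """Per-cycle mode: mean of each measure over the movement cycles."""
    if not cycles:
        raise ValueError("no cycles given")
    vecs = np.stack([extract_features(c).as_array() for c in cycles])
    mean = vecs.mean(axis=0)
    kw = dict(zip(FEATURE_NAMES, map(float, mean)))
    return FeatureVector(n_samples=int(sum(c.size for c in cycles)), **kw)


@dataclass(frozen=True)
class CaseRecord:
    """One classification case: signal measures + demographic covariates."""

    case_id: str
    features: FeatureVector
    age: float
    sex: int        # 0 = female, 1 = male
    bmi: float
    chain: Chain
    label: Group


def build_case(features: FeatureVector, subject: SubjectProfile, chain: Chain,
               case_id: str | None = None) -> CaseRecord:
    """Attach covariates and the binary label (any ICRS grade 1-4 -> OA)."""
    for attr in ("age", "sex", "bmi"):
        if getattr(subject, attr) is None:
            raise ValueError(f"missing covariate: {attr}")
    return CaseRecord(
        case_id=case_id or f"{subject.subject_id}-{chain.value}",
        features=features,
        age=subject.age,
        sex=1 if subject.sex.value == "M" else 0,
        bmi=subject.bmi,
        chain=chain,
        label=subject.group,
    )
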