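"""End-to-end orchestration of the three classification variants.

Variant I analyzes open-kinetic-chain recordings, variant II closed, and
variant III stacks both chains as separate observations with a 0/1 chain
indicator input.  One master seed fans out to per-stage sub-seeds through a
fixed counter scheme (SeedSequence([master, stage_code, index])), so a run
is fully reproducible from its manifest.

The feature-selection stage weights only the 12 signal measures; the
demographic covariates (age, sex, BMI) are always part of the classifier
input, as is the chain indicator in variant III.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from . import io as vio
from .cohort import Cohort, generate_cohort
from .emd import EEMDParams, SiftParams
from .evaluation import EvaluationReport, evaluate
from .features import FEATURE_NAMES, CaseRecord, build_case, extract_features
from .nca import LabeledDataset, NCAModel, fit_nca
from .networks import (Family, SplitConfig, TrainedNetwork, model_search,
                       predict_proba, split_dataset, train_mlp, NetworkSpec,
                       ErrorFunction)
from .preprocess import preprocess_recording
from .types import Chain, GeneratorConfig, Group

# stage codes of the seed fan-out
_STAGE_COHORT = 1
_STAGE_EEMD = 2
_STAGE_NCA = 3
_STAGE_SPLIT = 4
_STAGE_MLP = 5
_STAGE_RBF = 6
_STAGE_PERMUTE = 7

COVARIATES = ["age", "sex", "bmi"]


class Variant(str, Enum):
    I = "I"
    II = "II"
    III = "III"


VARIANT_CHAINS = {
    Variant.I: (Chain.OKC,),
    Variant.II: (Chain.CKC,),
    Variant.III: (Chain.OKC, Chain.CKC),
}


def stage_seed(master: int, stage: int, index: int = 0) -> int:
    """Deterministic sub-seed below 2**31."""
    ss = np.random.SeedSequence([master & 0x7FFFFFFF, stage, index])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class NCASettings:
    sigma: float = 1.0
    lam_grid: list[float] | None = None
    n_folds: int = 5
    threshold_frac: float = 0.05


@dataclass
class PipelineConfig:
    cohort: GeneratorConfig = field(default_factory=GeneratorConfig)
    eemd: EEMDParams = field(default_factory=EEMDParams)
    nca: NCASettings = field(default_factory=NCASettings)
    split: SplitConfig = field(default_factory=SplitConfig)
    variant: Variant = Variant.I
    mlp_grid: list[dict] | None = None
    rbf_grid: list[dict] | None = None
    output_dir: str | None = None
    seed: int = 0

    def resolved(self) -> "PipelineConfig":
        """Fan the master seed out to the stage configs."""
        return dataclasses.replace(
            self,
            cohort=dataclasses.replace(self.cohort,
                                       seed=stage_seed(self.seed, _STAGE_COHORT)),
            split=dataclasses.replace(self.split,
                                      seed=stage_seed(self.seed, _STAGE_SPLIT)),
        )


def config_from_dict(d: dict) -> PipelineConfig:
    kwargs: dict = {}
    if "cohort" in d:
        kwargs["cohort"] = GeneratorConfig(**{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in d["cohort"].items()})
    if "eemd" in d:
        e = dict(d["eemd"])
        sift = e.pop("sift", None)
        kwargs["eemd"] = EEMDParams(**e, **({"sift": SiftParams(**sift)} if sift else {}))
    if "nca" in d:
        kwargs["nca"] = NCASettings(**d["nca"])
    if "split" in d:
        kwargs["split"] = SplitConfig(**d["split"])
    for key in ("variant", "mlp_grid", "rbf_grid", "output_dir", "seed"):
        if key in d:
            kwargs[key] = Variant(d[key]) if key == "variant" else d[key]
    return PipelineConfig(**kwargs)


def config_from_yaml(path: str) -> PipelineConfig:
    import yaml
    with open(path, encoding="utf-8") as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def cases_from_cohort(cohort: Cohort, eemd_params: EEMDParams,
                      chains: tuple[Chain, ...], master_seed: int
                      ) -> list[CaseRecord]:
    """Preprocess and featurize every recording of the requested chains."""
    cases = []
    wanted = [r for r in cohort.recordings if r.chain in chains]
    for i, rec in enumerate(sorted(wanted, key=lambda r: r.recording_id)):
        params = dataclasses.replace(
            eemd_params, seed=stage_seed(master_seed, _STAGE_EEMD, i))
        pp = preprocess_recording(rec, params)
        fv = extract_features(pp.concatenated)
        cases.append(build_case(fv, rec.subject, rec.chain,
                                case_id=rec.recording_id))
    return cases


def cases_to_dataset(cases: list[CaseRecord], add_chain: bool) -> LabeledDataset:
    names = list(FEATURE_NAMES) + COVARIATES + (["chain_okc"] if add_chain else [])
    rows = []
    for c in cases:
        row = list(c.features.as_array()) + [c.age, c.sex, c.bmi]
        if add_chain:
            row.append(1.0 if c.chain == Chain.OKC else 0.0)
        rows.append(row)
    y = np.array([1 if c.label == Group.OA else 0 for c in cases])
    return LabeledDataset(X=np.array(rows), y=y, feature_names=names)


def _classifier_matrix(ds: LabeledDataset, signal_selected: list[int],
                       add_chain: bool) -> tuple[np.ndarray, list[str]]:
    """Selected signal measures + always-on covariates (+ chain indicator)."""
    n_sig = len(FEATURE_NAMES)
    cols = list(signal_selected) + list(range(n_sig, ds.d))
    return ds.X[:, cols], [ds.feature_names[i] for i in cols]


@dataclass
class VariantResult:
    config: PipelineConfig
    cases: list[CaseRecord]
    dataset: LabeledDataset
    nca_model: NCAModel
    input_names: list[str]
    splits: tuple[np.ndarray, np.ndarray, np.ndarray]
    mlp: TrainedNetwork
    rbf: TrainedNetwork
    mlp_board: pd.DataFrame
    rbf_board: pd.DataFrame
    mlp_report: EvaluationReport
    rbf_report: EvaluationReport

    def summary(self) -> dict:
        return {
            "variant": self.config.variant.value,
            "n_cases": len(self.cases),
            "selected_signal_features": [self.dataset.feature_names[i]
                                         for i in self.nca_model.selected
                                         if i < len(FEATURE_NAMES)],
            "classifier_inputs": self.input_names,
            "mlp": {"name": self.mlp.spec.name,
                    "test_accuracy_pct": self.mlp_report.accuracy_pct,
                    "auc": self.mlp_report.auc},
            "rbf": {"name": self.rbf.spec.name,
                    "test_accuracy_pct": self.rbf_report.accuracy_pct,
                    "auc": self.rbf_report.auc},
        }


def synthetic_study_config(seed: int = 1, variant: Variant = Variant.I,
                           n_trials: int = 16) -> PipelineConfig:
    """Conditions of the end-to-end synthetic classification experiment: the
    default 33 HC / 34 OA cohort with a 16-trial EEMD ensemble (the ensemble
    is the one problem-size reduction relative to the acquisition protocol's
    100-trial default; see the methods note)."""
    return PipelineConfig(eemd=EEMDParams(n_trials=n_trials),
                          variant=variant, seed=seed)


def run_variant(cfg: PipelineConfig) -> VariantResult:
    """generate -> preprocess -> features -> NCA -> model search -> evaluate."""
    cfg = cfg.resolved()
    chains = VARIANT_CHAINS[cfg.variant]
    cohort = generate_cohort(cfg.cohort, chains=chains)
    cases = cases_from_cohort(cohort, cfg.eemd, chains, cfg.seed)
    add_chain = cfg.variant == Variant.III
    ds = cases_to_dataset(cases, add_chain=add_chain)

    # NCA weights the 12 signal measures only
    sig_ds = LabeledDataset(X=ds.X[:, : len(FEATURE_NAMES)], y=ds.y,
                            feature_names=list(FEATURE_NAMES))
    nca_model = fit_nca(
        sig_ds, sigma=cfg.nca.sigma,
        lam_grid=None if cfg.nca.lam_grid is None else np.asarray(cfg.nca.lam_grid),
        n_folds=cfg.nca.n_folds, seed=stage_seed(cfg.seed, _STAGE_NCA),
        threshold_frac=cfg.nca.threshold_frac)

    X, input_names = _classifier_matrix(ds, nca_model.selected, add_chain)
    splits = split_dataset(ds.y, cfg.split)
    tr, te, va = splits

    mlp, mlp_board = model_search(X, ds.y, Family.MLP, splits,
                                  grid=cfg.mlp_grid,
                                  seed=stage_seed(cfg.seed, _STAGE_MLP))
    rbf, rbf_board = model_search(X, ds.y, Family.RBF, splits,
                                  grid=cfg.rbf_grid,
                                  seed=stage_seed(cfg.seed, _STAGE_RBF))

    mlp_rep = evaluate(ds.y[te], predict_proba(mlp, X[te])[:, 1])
    rbf_rep = evaluate(ds.y[te], predict_proba(rbf, X[te])[:, 1])

    result = VariantResult(
        config=cfg, cases=cases, dataset=ds, nca_model=nca_model,
        input_names=input_names, splits=splits,
        mlp=mlp, rbf=rbf, mlp_board=mlp_board, rbf_board=rbf_board,
        mlp_report=mlp_rep, rbf_report=rbf_rep)
    if cfg.output_dir:
        write_artifacts(result, cfg.output_dir)
    return result


def permutation_control(result: VariantResult, seed: int | None = None,
                        n_permutations: int = 5) -> float:
    """Chance-level control: retrain an MLP on label-permuted data and return
    the mean balanced test accuracy (percent) over permutation replicates.

    Balanced accuracy (mean of per-class accuracies) is used because the
    cohort is class-imbalanced (bilateral controls vs one operated knee), so
    plain accuracy has a chance level at the majority-class share rather
    than 50%; balanced accuracy centers at 50% under label permutation for
    any class prior.
    """
    cfg = result.config
    if seed is None:
        seed = stage_seed(cfg.seed, _STAGE_PERMUTE)
    X = result.dataset.X[:, [result.dataset.feature_names.index(n)
                             for n in result.input_names]]
    tr, te, va = result.splits
    spec = NetworkSpec(family=Family.MLP, n_in=X.shape[1], n_hidden=16,
                       hidden_activation="logistic",
                       error_function=ErrorFunction.ENTROPY, max_iter=200)
    scores = []
    for rep in range(n_permutations):
        rep_seed = stage_seed(seed, _STAGE_PERMUTE, rep)
        rng = np.random.default_rng(rep_seed)
        y_perm = rng.permutation(result.dataset.y)
        model = train_mlp(spec, X[tr], y_perm[tr], X[va], y_perm[va],
                          seed=rep_seed)
        pred = np.argmax(predict_proba(model, X[te]), axis=1)
        accs = [np.mean(pred[y_perm[te] == c] == c)
                for c in np.unique(y_perm[te])]
        scores.append(100.0 * float(np.mean(accs)))
    return float(np.mean(scores))


def write_artifacts(result: VariantResult, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    cfg = result.config
    vio.write_feature_table(result.cases, os.path.join(out_dir, "feature_table.csv"))
    result.nca_model.weight_table().to_csv(
        os.path.join(out_dir, "nca_weights.csv"), index=False,
        float_format="%.12g", lineterminator="\n")
    result.mlp_board.to_csv(os.path.join(out_dir, "leaderboard_mlp.csv"),
                            index=False, float_format="%.6g", lineterminator="\n")
    result.rbf_board.to_csv(os.path.join(out_dir, "leaderboard_rbf.csv"),
                            index=False, float_format="%.6g", lineterminator="\n")
    vio.write_report(result.mlp_report, os.path.join(out_dir, "report_mlp.json"))
    vio.write_report(result.rbf_report, os.path.join(out_dir, "report_rbf.json"))
    manifest = {
        "variant": cfg.variant.value,
        "seed": cfg.seed,
        "cohort": dataclasses.asdict(cfg.cohort),
        "eemd": {"noise_std": cfg.eemd.noise_std, "n_trials": cfg.eemd.n_trials,
                 "seed": cfg.eemd.seed,
                 "sift": dataclasses.asdict(cfg.eemd.sift)},
        "nca": dataclasses.asdict(cfg.nca),
        "split": dataclasses.asdict(cfg.split),
        "summary": result.summary(),
        "models": {"mlp": result.mlp.serializable(),
                   "rbf": result.rbf.serializable()},
    }
    with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8",
              newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
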