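"""Neighborhood component analysis feature weighting and selection.

NCA learns one non-negative-squared weight per feature by maximizing the
expected leave-one-out accuracy of a soft nearest-neighbor classifier.  The
formulation used here (the feature-selection variant of NCA):

    D_w(x_i, x_j) = sum_l w_l^2 |x_il - x_jl|          (weighted L1)
    kappa(z)      = exp(-z / sigma)                    (kernel width sigma)
    p_ij = kappa(D_w(x_i, x_j)) / sum_{k != i} kappa(D_w(x_i, x_k)),  p_ii = 0
    p_i  = sum_{j != i} 1[y_i = y_j] p_ij
    F(w) = sum_i p_i - lambda sum_l w_l^2

with the L2 penalty lambda tuned by cross-validation.  The gradient follows
from the chain rule (A^l_ij = |x_il - x_jl|):

    dF/dw_l = (2 w_l / sigma) sum_i [ p_i sum_k p_ik A^l_ik
                                      - sum_j 1[y_i=y_j] p_ij A^l_ij ] - 2 lambda w_l

and is verified against central finite differences in the test suite.

Features are standardized (training folds only) before weighting because the
inputs mix units (years of age against dimensionless signal moments).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

DEFAULT_SIGMA = 1.0
DEFAULT_THRESHOLD_FRAC = 0.05
MAX_ITER = 400
REL_TOL = 1e-6


@dataclass
class LabeledDataset:
    """Feature matrix with class labels; the NCA and classifier substrate."""

    X: np.ndarray               # (N, d)
    y: np.ndarray               # (N,) integer labels
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be (N, d) with matching labels")
        if self.X.shape[0] < 2:
            raise ValueError("need at least two observations")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must equal feature dimension")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


@dataclass
class NCAModel:
    w: np.ndarray
    sigma: float
    lam: float
    objective: float
    cv_table: pd.DataFrame
    selected: list[int]
    feature_names: list[str]
    scaler_mean: np.ndarray = field(default_factory=lambda: np.empty(0))
    scaler_std: np.ndarray = field(default_factory=lambda: np.empty(0))

    def weight_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": self.feature_names,
            "w": self.w,
            "w_squared": self.w**2,
            "selected": [i in self.selected for i in range(self.w.size)],
        })


def weighted_distance(xi: np.ndarray, xj: np.ndarray, w: np.ndarray) -> float:
    """sum_l w_l^2 |x_il - x_jl| (weighted L1 with squared weights)."""
    return float(np.sum(w**2 * np.abs(np.asarray(xi) - np.asarray(xj))))


def kernel(z, sigma: float):
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return np.exp(-np.asarray(z, dtype=float) / sigma)


def _abs_diffs(X: np.ndarray) -> np.ndarray:
    """A[l, i, j] = |x_il - x_jl|, shape (d, N, N)."""
    return np.abs(X.T[:, :, None] - X.T[:, None, :])


def _pij(A: np.ndarray, w: np.ndarray, sigma: float) -> np.ndarray:
    D = np.tensordot(w**2, A, axes=(0, 0))      # (N, N)
    # p_ij is a row softmax of -D/sigma (diagonal excluded); shift each row by
    # its off-diagonal minimum so the exponentials cannot all underflow
    np.fill_diagonal(D, np.inf)
    shift = D.min(axis=1, keepdims=True)
    K = np.exp(-(D - shift) / sigma)
    np.fill_diagonal(K, 0.0)
    return K / K.sum(axis=1, keepdims=True)


def loo_probabilities(dataset: LabeledDataset, w: np.ndarray, sigma: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out neighbor probabilities p_ij and per-point accuracies p_i."""
    A = _abs_diffs(dataset.X)
    P = _pij(A, np.asarray(w, dtype=float), sigma)
    Y = (dataset.y[:, None] == dataset.y[None, :]).astype(float)
    return P, (P * Y).sum(axis=1)


def objective(dataset: LabeledDataset, w: np.ndarray, sigma: float,
              lam: float) -> float:
    """F(w) = sum_i p_i - lambda * sum_l w_l^2."""
    _, p = loo_probabilities(dataset, w, sigma)
    return float(p.sum() - lam * np.sum(np.asarray(w, dtype=float) ** 2))


def _objective_and_grad(A: np.ndarray, Y: np.ndarray, w: np.ndarray,
                        sigma: float, lam: float) -> tuple[float, np.ndarray]:
    P = _pij(A, w, sigma)
    p = (P * Y).sum(axis=1)
    F = float(p.sum() - lam * np.sum(w**2))
    # sum_i [ p_i sum_k p_ik A_ik - sum_j y_ij p_ij A_ij ]  per feature l
    PA = np.einsum("ij,lij->li", P, A)              # (d, N): sum_k p_ik A^l_ik
    PYA = np.einsum("ij,lij->li", P * Y, A)         # (d, N): sum_j y_ij p_ij A^l_ij
    core = PA @ p - PYA.sum(axis=1)                 # (d,)
    grad = (2.0 * w / sigma) * core - 2.0 * lam * w
    return F, grad


def objective_gradient(dataset: LabeledDataset, w: np.ndarray, sigma: float,
                       lam: float) -> np.ndarray:
    A = _abs_diffs(dataset.X)
    Y = (dataset.y[:, None] == dataset.y[None, :]).astype(float)
    _, g = _objective_and_grad(A, Y, np.asarray(w, dtype=float), sigma, lam)
    return g


def _ascend(A: np.ndarray, Y: np.ndarray, sigma: float, lam: float,
            w0: np.ndarray) -> tuple[np.ndarray, float]:
    """Gradient ascent with backtracking line search; F never decreases."""
    w = w0.copy()
    F, g = _objective_and_grad(A, Y, w, sigma, lam)
    step = 1.0
    for _ in range(MAX_ITER):
        gnorm2 = float(np.sum(g**2))
        if gnorm2 == 0:
            break
        t = step
        while t > 1e-12:
            w_new = w + t * g
            F_new, g_new = _objective_and_grad(A, Y, w_new, sigma, lam)
            if F_new >= F + 1e-4 * t * gnorm2:
                break
            t *= 0.5
        else:
            break
        if abs(F_new - F) <= REL_TOL * max(abs(F), 1.0):
            w, F, g = w_new, F_new, g_new
            break
        w, F, g = w_new, F_new, g_new
        step = min(t * 2.0, 1e3)
    return w, F


def _standardize(X: np.ndarray, mean: np.ndarray | None = None,
                 std: np.ndarray | None = None):
    if mean is None:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std = np.where(std == 0, 1.0, std)
    return (X - mean) / std, mean, std


def _holdout_loss(Xtr, ytr, Xva, yva, w, sigma) -> float:
    """1 - mean soft-NN accuracy of held-out points scored against the
    training fold."""
    D = np.tensordot(w**2, np.abs(Xva.T[:, :, None] - Xtr.T[:, None, :]), axes=(0, 0))
    K = np.exp(-(D - D.min(axis=1, keepdims=True)) / sigma)
    num = (K * (yva[:, None] == ytr[None, :])).sum(axis=1)
    den = K.sum(axis=1)
    return float(1.0 - np.mean(num / np.maximum(den, 1e-300)))


def default_lambda_grid(n: int) -> np.ndarray:
    return np.logspace(-4, 0, 10) / n


def fit_nca(dataset: LabeledDataset, sigma: float = DEFAULT_SIGMA,
            lam_grid: np.ndarray | None = None, n_folds: int = 5,
            seed: int = 0,
            threshold_frac: float = DEFAULT_THRESHOLD_FRAC) -> NCAModel:
    """Cross-validate lambda, refit on the full data, select features."""
    if lam_grid is None:
        lam_grid = default_lambda_grid(dataset.n)
    lam_grid = np.asarray(lam_grid, dtype=float)
    if lam_grid.size == 0:
        raise ValueError("empty lambda grid")
    if not (dataset.n >= n_folds >= 2):
        raise ValueError("need N >= n_folds >= 2")

    w0 = np.ones(dataset.d)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    losses = np.zeros(lam_grid.size)
    folds = list(skf.split(dataset.X, dataset.y))
    for tr, va in folds:
        Xtr, mean, std = _standardize(dataset.X[tr])
        Xva, _, _ = _standardize(dataset.X[va], mean, std)
        A = _abs_diffs(Xtr)
        Y = (dataset.y[tr][:, None] == dataset.y[tr][None, :]).astype(float)
        for k, lam in enumerate(lam_grid):
            w, _ = _ascend(A, Y, sigma, lam, w0)
            losses[k] += _holdout_loss(Xtr, dataset.y[tr], Xva, dataset.y[va],
                                       w, sigma)
    losses /= len(folds)
    best = int(np.argmin(losses))
    lam = float(lam_grid[best])

    Xs, mean, std = _standardize(dataset.X)
    A = _abs_diffs(Xs)
    Y = (dataset.y[:, None] == dataset.y[None, :]).astype(float)
    w, F = _ascend(A, Y, sigma, lam, w0)

    model = NCAModel(
        w=w, sigma=sigma, lam=lam, objective=F,
        cv_table=pd.DataFrame({"lambda": lam_grid, "mean_val_loss": losses}),
        selected=[], feature_names=list(dataset.feature_names),
        scaler_mean=mean, scaler_std=std,
    )
    model.selected = select_features(model, threshold_frac)
    return model


def select_features(model: NCAModel, threshold_frac: float) -> list[int]:
    """Indices l with w_l^2 >= threshold_frac * max w_l^2."""
    w2 = model.w**2
    top = w2.max()
    if top == 0:
        import warnings
        warnings.warn("all NCA weights are zero; nothing selected", RuntimeWarning)
        return []
    return [int(i) for i in np.nonzero(w2 >= threshold_frac * top)[0]]
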