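"""MLP and RBF network classifiers for binary HC/OA assignment.

Two shallow network families, mirroring the automated-search setting they
are benchmarked against:

* MLP: one hidden layer (linear / logistic / tanh / exponential / gauss
  activation), softmax / exponential / linear output, trained by a
  quasi-Newton (BFGS-family) routine on cross-entropy ("entropy") or
  sum-of-squares ("SOS") loss, with the best-validation-error iterate
  retained.  Network names follow the "MLP n_in-n_hidden-2" convention.
* RBF: Gaussian hidden units around k-means centers with per-center widths
  (mean distance to the 2 nearest other centers), output layer fit as a
  convex softmax/cross-entropy problem ("RBFT"-style recipe).

Inputs are standardized with training-set statistics inside the model, so
rescaling a raw feature column changes no prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.cluster import KMeans


class Family(str, Enum):
    MLP = "MLP"
    RBF = "RBF"


class ErrorFunction(str, Enum):
    SOS = "SOS"
    ENTROPY = "Entropy"


_HIDDEN_ACTS = ("linear", "logistic", "tanh", "exponential", "gauss")
_OUTPUT_ACTS = ("softmax", "exponential", "linear")


@dataclass(frozen=True)
class NetworkSpec:
    family: Family
    n_in: int
    n_hidden: int
    hidden_activation: str = "logistic"
    output_activation: str = "softmax"
    error_function: ErrorFunction = ErrorFunction.ENTROPY
    max_iter: int = 200
    n_out: int = 2

    def __post_init__(self) -> None:
        if self.hidden_activation not in _HIDDEN_ACTS:
            raise ValueError(f"unknown hidden activation {self.hidden_activation}")
        if self.output_activation not in _OUTPUT_ACTS:
            raise ValueError(f"unknown output activation {self.output_activation}")
        if self.family == Family.RBF and self.hidden_activation != "gauss":
            raise ValueError("RBF networks require gauss hidden activation")
        if self.n_out != 2:
            raise ValueError("binary classifier: n_out must be 2")

    @property
    def name(self) -> str:
        return f"{self.family.value} {self.n_in}-{self.n_hidden}-{self.n_out}"

    @property
    def algorithm(self) -> str:
        return "RBFT" if self.family == Family.RBF else f"BFGS {self.max_iter}"


@dataclass
class TrainedNetwork:
    spec: NetworkSpec
    parameters: dict[str, np.ndarray]
    input_mean: np.ndarray
    input_std: np.ndarray
    training_log: list[float] = field(default_factory=list)

    def serializable(self) -> dict:
        return {
            "spec": {
                "family": self.spec.family.value,
                "n_in": self.spec.n_in,
                "n_hidden": self.spec.n_hidden,
                "hidden_activation": self.spec.hidden_activation,
                "output_activation": self.spec.output_activation,
                "error_function": self.spec.error_function.value,
                "max_iter": self.spec.max_iter,
            },
            "parameters": {k: v.tolist() for k, v in self.parameters.items()},
            "input_mean": self.input_mean.tolist(),
            "input_std": self.input_std.tolist(),
        }


@dataclass(frozen=True)
class SplitConfig:
    train_frac: float = 0.70
    test_frac: float = 0.15
    val_frac: float = 0.15
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if abs(self.train_frac + self.test_frac + self.val_frac - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def split_dataset(y: np.ndarray, cfg: SplitConfig
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive (train, test, validation) index sets."""
    y = np.asarray(y)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 cases to split")
    rng = np.random.default_rng(cfg.seed)
    groups = [np.nonzero(y == c)[0] for c in np.unique(y)] if cfg.stratified \
        else [np.arange(n)]
    train, test, val = [], [], []
    for idx in groups:
        idx = idx.copy()
        rng.shuffle(idx)
        n_tr = int(round(cfg.train_frac * idx.size))
        n_te = int(round(cfg.test_frac * idx.size))
        if cfg.stratified and (n_tr == 0 or n_te == 0 or idx.size - n_tr - n_te == 0):
            raise ValueError("stratified split leaves a subset empty of one class")
        train.append(idx[:n_tr])
        test.append(idx[n_tr:n_tr + n_te])
        val.append(idx[n_tr + n_te:])
    return (np.sort(np.concatenate(train)), np.sort(np.concatenate(test)),
            np.sort(np.concatenate(val)))


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "linear":
        return z
    if name == "logistic":
        return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
    if name == "tanh":
        return np.tanh(z)
    if name == "exponential":
        return np.exp(np.clip(z, -500, 500))
    if name == "gauss":
        return np.exp(-z**2)
    raise ValueError(name)


def _act_deriv(name: str, z: np.ndarray, a: np.ndarray) -> np.ndarray:
    if name == "linear":
        return np.ones_like(z)
    if name == "logistic":
        return a * (1.0 - a)
    if name == "tanh":
        return 1.0 - a**2
    if name == "exponential":
        return a
    if name == "gauss":
        return -2.0 * z * a
    raise ValueError(name)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _one_hot(y: np.ndarray) -> np.ndarray:
    Y = np.zeros((y.size, 2))
    Y[np.arange(y.size), y.astype(int)] = 1.0
    return Y


class _MLPCore:
    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        self.shapes = [(spec.n_in, spec.n_hidden), (spec.n_hidden,),
                       (spec.n_hidden, spec.n_out), (spec.n_out,)]

    def unpack(self, theta: np.ndarray):
        out, o = [], 0
        for shp in self.shapes:
            size = int(np.prod(shp))
            out.append(theta[o:o + size].reshape(shp))
            o += size
        return out

    def forward(self, theta: np.ndarray, X: np.ndarray):
        W1, b1, W2, b2 = self.unpack(theta)
        z1 = X @ W1 + b1
        a1 = _act(self.spec.hidden_activation, z1)
        z2 = a1 @ W2 + b2
        if self.spec.output_activation == "softmax":
            a2 = _softmax(z2)
        else:
            a2 = _act(self.spec.output_activation, z2)
        return z1, a1, z2, a2

    def loss_grad(self, theta: np.ndarray, X: np.ndarray, Y: np.ndarray):
        spec = self.spec
        W1, b1, W2, b2 = self.unpack(theta)
        z1, a1, z2, a2 = self.forward(theta, X)
        n = X.shape[0]
        if spec.error_function == ErrorFunction.ENTROPY:
            if spec.output_activation != "softmax":
                raise ValueError("entropy loss requires softmax output")
            loss = -float(np.sum(Y * np.log(np.maximum(a2, 1e-300)))) / n
            delta2 = (a2 - Y) / n
        else:  # SOS
            loss = float(np.sum((a2 - Y) ** 2)) / n
            dL = 2.0 * (a2 - Y) / n
            if spec.output_activation == "softmax":
                # softmax jacobian: a*(dL - sum(dL*a))
                delta2 = a2 * (dL - np.sum(dL * a2, axis=1, keepdims=True))
            else:
                delta2 = dL * _act_deriv(spec.output_activation, z2, a2)
        dW2 = a1.T @ delta2
        db2 = delta2.sum(axis=0)
        delta1 = (delta2 @ W2.T) * _act_deriv(spec.hidden_activation, z1, a1)
        dW1 = X.T @ delta1
        db1 = delta1.sum(axis=0)
        grad = np.concatenate([dW1.ravel(), db1.ravel(), dW2.ravel(), db2.ravel()])
        return loss, grad


def _standardize_fit(X: np.ndarray):
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std == 0, 1.0, std)
    return mean, std


def _glorot_init(spec: NetworkSpec, rng: np.random.Generator) -> np.ndarray:
    parts = []
    for fan_in, fan_out in ((spec.n_in, spec.n_hidden), (spec.n_hidden, spec.n_out)):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        parts.append(rng.uniform(-lim, lim, fan_in * fan_out))
        parts.append(np.zeros(fan_out))
    return np.concatenate([parts[0], parts[1], parts[2], parts[3]])


def train_mlp(spec: NetworkSpec, X_train: np.ndarray, y_train: np.ndarray,
              X_val: np.ndarray | None = None, y_val: np.ndarray | None = None,
              seed: int = 0) -> TrainedNetwork:
    """Quasi-Newton training capped at spec.max_iter iterations; the iterate
    with the lowest validation classification error is retained."""
    if spec.family != Family.MLP:
        raise ValueError("spec.family must be MLP")
    if X_train.shape[1] != spec.n_in:
        raise ValueError("n_in does not match data")
    mean, std = _standardize_fit(X_train)
    Xs = (X_train - mean) / std
    Y = _one_hot(y_train)
    core = _MLPCore(spec)
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 17])
    theta0 = _glorot_init(spec, rng)

    has_val = X_val is not None and len(X_val) > 0
    Xv = (X_val - mean) / std if has_val else None
    log: list[float] = []
    best = {"theta": theta0.copy(), "err": np.inf}

    def track(theta):
        loss, _ = core.loss_grad(theta, Xs, Y)
        log.append(loss)
        if has_val:
            _, _, _, a2 = core.forward(theta, Xv)
            err = float(np.mean(np.argmax(a2, axis=1) != y_val))
        else:
            err = loss
        if err < best["err"]:
            best["err"] = err
            best["theta"] = theta.copy()

    track(theta0)
    res = minimize(core.loss_grad, theta0, args=(Xs, Y), jac=True,
                   method="L-BFGS-B", callback=track,
                   options={"maxiter": spec.max_iter})
    if not np.all(np.isfinite(res.x)):
        raise FloatingPointError("non-finite parameters after MLP training")
    track(res.x)
    W1, b1, W2, b2 = core.unpack(best["theta"])
    return TrainedNetwork(
        spec=spec, parameters={"W1": W1, "b1": b1, "W2": W2, "b2": b2},
        input_mean=mean, input_std=std, training_log=log)


def train_rbf(spec: NetworkSpec, X_train: np.ndarray, y_train: np.ndarray,
              X_val: np.ndarray | None = None, y_val: np.ndarray | None = None,
              seed: int = 0, width_scale: float = 1.0) -> TrainedNetwork:
    """k-means centers, per-center Gaussian widths, convex softmax output fit."""
    if spec.family != Family.RBF:
        raise ValueError("spec.family must be RBF")
    n_train = X_train.shape[0]
    if spec.n_hidden > n_train:
        raise ValueError("n_hidden cannot exceed the training-set size")
    mean, std = _standardize_fit(X_train)
    Xs = (X_train - mean) / std

    if spec.n_hidden == n_train:
        centers = Xs.copy()
    else:
        km = KMeans(n_clusters=spec.n_hidden, n_init=4,
                    random_state=seed & 0x7FFFFFFF)
        centers = km.fit(Xs).cluster_centers_

    if centers.shape[0] == 1:
        widths = np.array([max(float(np.mean(
            np.linalg.norm(Xs - centers[0], axis=1))), 1e-6)])
    else:
        dc = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
        np.fill_diagonal(dc, np.inf)
        p = min(2, centers.shape[0] - 1)
        widths = np.sort(dc, axis=1)[:, :p].mean(axis=1)
        widths = np.maximum(widths, 1e-6)
    widths = widths * width_scale

    Phi = _rbf_hidden(Xs, centers, widths)

    # convex cross-entropy fit of the output layer (softmax), tiny ridge for
    # conditioning only
    Y = _one_hot(y_train)
    h = spec.n_hidden
    ridge = 1e-8

    def f(theta):
        W = theta[: h * 2].reshape(h, 2)
        b = theta[h * 2:]
        P = _softmax(Phi @ W + b)
        loss = -float(np.sum(Y * np.log(np.maximum(P, 1e-300)))) / n_train
        loss += ridge * float(np.sum(W**2))
        delta = (P - Y) / n_train
        gW = Phi.T @ delta + 2 * ridge * W
        gb = delta.sum(axis=0)
        return loss, np.concatenate([gW.ravel(), gb])

    res = minimize(f, np.zeros(h * 2 + 2), jac=True, method="L-BFGS-B",
                   options={"maxiter": 500})
    W = res.x[: h * 2].reshape(h, 2)
    b = res.x[h * 2:]
    return TrainedNetwork(
        spec=spec,
        parameters={"centers": centers, "widths": widths, "W": W, "b": b},
        input_mean=mean, input_std=std, training_log=[float(res.fun)])


def _rbf_hidden(Xs: np.ndarray, centers: np.ndarray, widths: np.ndarray) -> np.ndarray:
    d2 = ((Xs[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2.0 * widths**2))


def predict_proba(model: TrainedNetwork, X: np.ndarray) -> np.ndarray:
    """Per-case class probabilities (columns: HC, OA); rows sum to 1."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.input_mean.size:
        raise ValueError("feature dimension mismatch")
    Xs = (X - model.input_mean) / model.input_std
    if model.spec.family == Family.RBF:
        p = model.parameters
        out = _rbf_hidden(Xs, p["centers"], p["widths"]) @ p["W"] + p["b"]
        return _softmax(out)
    p = model.parameters
    z1 = Xs @ p["W1"] + p["b1"]
    a1 = _act(model.spec.hidden_activation, z1)
    z2 = a1 @ p["W2"] + p["b2"]
    if model.spec.output_activation in ("softmax", "exponential"):
        # exponential outputs normalized to a distribution == softmax of z2
        return _softmax(z2)
    a2 = z2 - z2.min(axis=1, keepdims=True) + 1e-12   # linear: shift then normalize
    return a2 / a2.sum(axis=1, keepdims=True)


def predict(model: TrainedNetwork, X: np.ndarray) -> np.ndarray:
    return np.argmax(predict_proba(model, X), axis=1)


def accuracy(model: TrainedNetwork, X: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(predict(model, X) == y))


DEFAULT_MLP_GRID: tuple[dict, ...] = (
    {"n_hidden": 3, "hidden_activation": "tanh", "error_function": "Entropy",
     "output_activation": "softmax", "max_iter": 103},
    {"n_hidden": 16, "hidden_activation": "logistic", "error_function": "Entropy",
     "output_activation": "softmax", "max_iter": 200},
    {"n_hidden": 40, "hidden_activation": "linear", "error_function": "SOS",
     "output_activation": "exponential", "max_iter": 25},
    {"n_hidden": 40, "hidden_activation": "logistic", "error_function": "Entropy",
     "output_activation": "softmax", "max_iter": 200},
)

DEFAULT_RBF_GRID: tuple[dict, ...] = (
    {"n_hidden": 14}, {"n_hidden": 35}, {"n_hidden": 40},
)


def model_search(X: np.ndarray, y: np.ndarray, family: Family,
                 splits: tuple[np.ndarray, np.ndarray, np.ndarray],
                 grid: Sequence[dict] | None = None, seed: int = 0
                 ) -> tuple[TrainedNetwork, pd.DataFrame]:
    """Train every candidate, rank by validation accuracy, return the best
    plus a leaderboard in the 'FAMILY n_in-n_hidden-2' naming convention.

    Validation accuracy on a small held-out set is coarse (many candidates
    tie at 100%), so ties are broken by the mean predicted probability of
    the true class on the validation set — a continuous confidence margin —
    and only then by name.
    """
    if grid is None:
        grid = DEFAULT_MLP_GRID if family == Family.MLP else DEFAULT_RBF_GRID
    if not grid:
        raise ValueError("empty model grid")
    tr, te, va = splits
    n_in = X.shape[1]
    rows, models, margins = [], [], []
    for cand in grid:
        kwargs = dict(cand)
        if family == Family.RBF:
            kwargs.setdefault("hidden_activation", "gauss")
            kwargs["n_hidden"] = min(kwargs["n_hidden"], tr.size)
        spec = NetworkSpec(family=family, n_in=n_in, **{
            k: (ErrorFunction(v) if k == "error_function" else v)
            for k, v in kwargs.items()})
        trainer = train_mlp if family == Family.MLP else train_rbf
        model = trainer(spec, X[tr], y[tr], X[va], y[va], seed=seed)
        rows.append({
            "name": spec.name,
            "learning_accuracy_pct": 100 * accuracy(model, X[tr], y[tr]),
            "testing_accuracy_pct": 100 * accuracy(model, X[te], y[te]),
            "validation_accuracy_pct": 100 * accuracy(model, X[va], y[va]),
            "algorithm": spec.algorithm,
            "error_function": spec.error_function.value,
            "hidden_activation": spec.hidden_activation,
            "output_activation": spec.output_activation,
        })
        models.append(model)
        p_val = predict_proba(model, X[va])
        margins.append(float(np.mean(p_val[np.arange(va.size), y[va]])))
    board = pd.DataFrame(rows)
    order = np.lexsort((board["name"].values, -np.asarray(margins),
                        -board["validation_accuracy_pct"].values))
    best = models[int(order[0])]
    return best, board
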