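"""Fusion of the four EEG features into a 0–100 depth-of-anesthesia index.

Two regressors are provided, both trained against a per-minute reference
index (BIS-like, 0–100):

* a feedforward neural network with the fixed 4-4-7-1 topology (four
  inputs, two hidden layers of four and seven logistic units, one
  logistic output rescaled to 0–100), trained by full-batch
  backpropagation with momentum and validation-based early stopping; and
* a linear ε-insensitive support-vector regression baseline.

Inputs are z-scored with statistics from the training set; targets are
scaled to [0, 1] for the network.  Both models are deterministic given a
seed and serialize to a plain JSON file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import IndexSeries
from .spectral import FeatureVector

__all__ = [
    "AnnHyper",
    "DoaModel",
    "train_ann",
    "train_svr",
    "predict_index",
    "hidden_nodes_heuristic",
    "features_to_matrix",
]

ANN_LAYERS = (4, 4, 7, 1)


def features_to_matrix(features: list[FeatureVector]) -> tuple[np.ndarray, np.ndarray]:
    """Stack feature vectors into an (n, 4) matrix plus minute indices.

    Raises if any entry is non-finite, naming the offending minute.
    """
    rows = []
    minutes = []
    for fv in features:
        arr = fv.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite feature at minute {fv.minute_index}: {arr}")
        rows.append(arr)
        minutes.append(fv.minute_index)
    return np.asarray(rows, float), np.asarray(minutes, int)


@dataclass
class AnnHyper:
    """Backpropagation settings: full-batch gradient descent with momentum."""

    learning_rate: float = 0.2
    momentum: float = 0.9
    max_epochs: int = 5000
    patience: int = 100
    validation_fraction: float = 0.1
    tol: float = 1e-7
    restarts: int = 3


@dataclass
class DoaModel:
    """A trained fusion regressor (ANN or linear SVR) with its input scaler."""

    kind: str  # "ann" | "svr"
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    feature_subset: tuple[int, ...] = (0, 1, 2, 3)
    # ann
    weights: list[np.ndarray] | None = None
    biases: list[np.ndarray] | None = None
    train_seed: int = 0
    loss_curve: list[float] = field(default_factory=list)
    # svr
    svr_w: np.ndarray | None = None
    svr_b: float = 0.0
    svr_C: float = 10.0
    svr_epsilon: float = 2.0
    output_range: tuple[float, float] = (0.0, 100.0)

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path) -> Path:
        d: dict = {
            "kind": self.kind,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
            "feature_subset": list(self.feature_subset),
            "train_seed": self.train_seed,
            "output_range": list(self.output_range),
        }
        if self.kind == "ann":
            d["layer_sizes"] = list(ANN_LAYERS)
            d["weights"] = [w.tolist() for w in self.weights]
            d["biases"] = [b.tolist() for b in self.biases]
        else:
            d["svr_w"] = self.svr_w.tolist()
            d["svr_b"] = self.svr_b
            d["svr_C"] = self.svr_C
            d["svr_epsilon"] = self.svr_epsilon
        path = Path(path)
        path.write_text(json.dumps(d))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "DoaModel":
        d = json.loads(Path(path).read_text())
        m = cls(
            kind=d["kind"],
            scaler_mean=np.asarray(d["scaler_mean"], float),
            scaler_sd=np.asarray(d["scaler_sd"], float),
            feature_subset=tuple(d["feature_subset"]),
            train_seed=d.get("train_seed", 0),
            output_range=tuple(d.get("output_range", (0.0, 100.0))),
        )
        if m.kind == "ann":
            m.weights = [np.asarray(w, float) for w in d["weights"]]
            m.biases = [np.asarray(b, float) for b in d["biases"]]
        else:
            m.svr_w = np.asarray(d["svr_w"], float)
            m.svr_b = float(d["svr_b"])
            m.svr_C = float(d["svr_C"])
            m.svr_epsilon = float(d["svr_epsilon"])
        return m


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward(
    X: np.ndarray, weights: list[np.ndarray], biases: list[np.ndarray]
) -> list[np.ndarray]:
    """Activations per layer; logistic units throughout, output in (0, 1)."""
    acts = [X]
    a = X
    for W, b in zip(weights, biases):
        a = _sigmoid(a @ W + b)
        acts.append(a)
    return acts


def _init_layers(sizes: tuple[int, ...], rng: np.random.Generator):
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = 1.0 / np.sqrt(fan_in)
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def _prepare_xy(
    features: list[FeatureVector] | np.ndarray,
    targets: IndexSeries | np.ndarray,
    drop_degenerate: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(features, np.ndarray):
        X = np.asarray(features, float)
        keep = np.ones(X.shape[0], bool)
    else:
        X, _ = features_to_matrix(features)
        keep = np.array([not (fv.flags & {"degenerate"}) for fv in features])
    y = targets.values if isinstance(targets, IndexSeries) else np.asarray(targets, float)
    if X.shape[0] != y.size:
        raise ValueError(f"{X.shape[0]} feature rows vs {y.size} targets")
    if np.any((y < 0) | (y > 100)):
        raise ValueError("targets must lie in [0, 100]")
    if drop_degenerate and not keep.all():
        X, y = X[keep], y[keep]
    return X, y


def _fit_scaler(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


def train_ann(
    features: list[FeatureVector] | np.ndarray,
    targets: IndexSeries | np.ndarray,
    hyper: AnnHyper | None = None,
    seed: int = 0,
    feature_subset: tuple[int, ...] | None = None,
) -> DoaModel:
    """Train the 4-4-7-1 network by full-batch backpropagation.

    Inputs are z-scored, targets mapped to [0, 1].  Gradient descent with
    momentum runs until the validation MSE (10% split, seeded) stops
    improving for ``patience`` epochs or ``max_epochs`` is reached.  The
    best-validation weights are kept.  Fully deterministic given the seed.
    Training is restarted from ``hyper.restarts`` seeded initializations
    and the run with the best validation loss wins — full-batch descent
    on a logistic net occasionally stalls on the initial plateau, and a
    fresh initialization is the reliable escape.
    When ``feature_subset`` restricts the inputs, the input layer shrinks
    accordingly (used by the ablation study); the hidden topology stays 4-7.
    """
    hyper = hyper or AnnHyper()
    X, y = _prepare_xy(features, targets)
    if X.shape[0] < 50:
        raise ValueError(f"need ≥ 50 training pairs, got {X.shape[0]}")
    subset = tuple(feature_subset) if feature_subset is not None else tuple(range(X.shape[1]))
    X = X[:, subset]
    mean, sd = _fit_scaler(X)
    Xs = (X - mean) / sd
    ys = (y / 100.0).reshape(-1, 1)

    master = np.random.default_rng(seed)
    best_run: tuple[float, list, list, list] | None = None
    for _ in range(max(hyper.restarts, 1)):
        run_seed = int(master.integers(0, 2**31 - 1))
        val_loss, weights, biases, curve = _train_once(Xs, ys, subset, hyper, run_seed)
        if best_run is None or val_loss < best_run[0]:
            best_run = (val_loss, weights, biases, curve)
    _, weights, biases, loss_curve = best_run
    return DoaModel(
        kind="ann",
        scaler_mean=mean,
        scaler_sd=sd,
        feature_subset=subset,
        weights=weights,
        biases=biases,
        train_seed=seed,
        loss_curve=loss_curve,
    )


def _train_once(
    Xs: np.ndarray, ys: np.ndarray, subset: tuple[int, ...], hyper: AnnHyper, seed: int
) -> tuple[float, list[np.ndarray], list[np.ndarray], list[float]]:
    rng = np.random.default_rng(seed)
    sizes = (len(subset),) + ANN_LAYERS[1:]
    weights, biases = _init_layers(sizes, rng)

    n = Xs.shape[0]
    n_val = max(int(round(hyper.validation_fraction * n)), 1)
    order = rng.permutation(n)
    val_idx, train_idx = order[:n_val], order[n_val:]
    Xt, yt = Xs[train_idx], ys[train_idx]
    Xv, yv = Xs[val_idx], ys[val_idx]

    vel_w = [np.zeros_like(W) for W in weights]
    vel_b = [np.zeros_like(b) for b in biases]
    best = (np.inf, [W.copy() for W in weights], [b.copy() for b in biases])
    stall = 0
    loss_curve: list[float] = []

    for _ in range(hyper.max_epochs):
        acts = _forward(Xt, weights, biases)
        err = acts[-1] - yt
        loss = float(np.mean(err**2))
        loss_curve.append(loss)

        delta = 2.0 * err / err.shape[0] * acts[-1] * (1 - acts[-1])
        for li in range(len(weights) - 1, -1, -1):
            grad_w = acts[li].T @ delta
            grad_b = delta.sum(axis=0)
            if li > 0:
                delta = (delta @ weights[li].T) * acts[li] * (1 - acts[li])
            vel_w[li] = hyper.momentum * vel_w[li] - hyper.learning_rate * grad_w
            vel_b[li] = hyper.momentum * vel_b[li] - hyper.learning_rate * grad_b
            weights[li] += vel_w[li]
            biases[li] += vel_b[li]

        val_pred = _forward(Xv, weights, biases)[-1]
        val_loss = float(np.mean((val_pred - yv) ** 2))
        if val_loss < best[0] - hyper.tol:
            best = (val_loss, [W.copy() for W in weights], [b.copy() for b in biases])
            stall = 0
        else:
            stall += 1
            if stall >= hyper.patience:
                break

    val_loss, weights, biases = best
    return val_loss, weights, biases, loss_curve


def train_svr(
    features: list[FeatureVector] | np.ndarray,
    targets: IndexSeries | np.ndarray,
    C: float = 10.0,
    epsilon: float = 2.0,
    feature_subset: tuple[int, ...] | None = None,
) -> DoaModel:
    """Linear ε-SVR baseline: minimizes ``½‖w‖² + C Σ(ξ⁻+ξ⁺)``.

    Solved via libsvm (scikit-learn); the primal weight vector is
    recovered from the dual coefficients as ``w = Σ β_n x_n``, so
    prediction is the plain linear form ``f(x) = w·x + b`` on z-scored
    inputs, clipped to [0, 100].
    """
    from sklearn.svm import SVR

    X, y = _prepare_xy(features, targets)
    subset = tuple(feature_subset) if feature_subset is not None else tuple(range(X.shape[1]))
    X = X[:, subset]
    mean, sd = _fit_scaler(X)
    Xs = (X - mean) / sd
    svr = SVR(kernel="linear", C=C, epsilon=epsilon)
    svr.fit(Xs, y)
    w = (svr.dual_coef_ @ svr.support_vectors_).ravel()  # w = Σ β_n x_n
    return DoaModel(
        kind="svr",
        scaler_mean=mean,
        scaler_sd=sd,
        feature_subset=subset,
        svr_w=w,
        svr_b=float(svr.intercept_[0]),
        svr_C=C,
        svr_epsilon=epsilon,
    )


def predict_index(
    model: DoaModel, features: list[FeatureVector] | np.ndarray
) -> IndexSeries:
    """Predict the 0–100 index for each input minute (clipped to range)."""
    if isinstance(features, np.ndarray):
        X = np.asarray(features, float)
        minutes = np.arange(X.shape[0])
    else:
        X, minutes = features_to_matrix(features)
        if minutes.size > 1 and np.any(np.diff(minutes) <= 0):
            minutes = np.arange(X.shape[0])
    X = X[:, model.feature_subset]
    Xs = (X - model.scaler_mean) / model.scaler_sd
    if model.kind == "ann":
        out = _forward(Xs, model.weights, model.biases)[-1].ravel() * 100.0
    elif model.kind == "svr":
        out = Xs @ model.svr_w + model.svr_b
    else:
        raise ValueError(f"unknown model kind {model.kind!r}")
    lo, hi = model.output_range
    return IndexSeries(values=np.clip(out, lo, hi), minute_offsets=minutes)


def hidden_nodes_heuristic(a: int, b: int, c: int) -> int:
    """Classic hidden-node rule of thumb ``d = a + b + c``.

    ``a``/``b`` are input/output node counts and ``c`` a regulation
    constant in 1..10.  Documents the search that motivates the 7-node
    second hidden layer (a=4, b=1, c=2); the 4-4-7-1 architecture itself
    is fixed.
    """
    if a < 1 or b < 1:
        raise ValueError("input and output counts must be ≥ 1")
    if not 1 <= c <= 10:
        raise ValueError("regulation constant c must lie in 1..10")
    return a + b + c
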