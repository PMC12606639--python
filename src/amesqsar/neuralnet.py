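"""Small fully connected classifiers over a fixed hyperparameter grid.

The model is a feed-forward network with rectifier (ReLU) hidden layers
and a logistic (sigmoid) output trained on binary cross-entropy, the
standard architecture for fingerprint-based QSAR classification.  The
hyperparameter grid is deliberately small: hidden layouts (512,),
(512, 128) or (512, 128, 8), optimizer Adamax or Adam, fixed learning
rate.  Training is implemented directly in NumPy so that runs are
bit-reproducible from a single integer seed.

Evaluation is by stratified k-fold cross-validation (default k=10),
reporting the six confusion-matrix scores per fold with mean +/- sd.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .metrics import MetricSet, compute_metrics, confusion_counts

__all__ = [
    "HIDDEN_GRID",
    "OPTIMIZERS",
    "NetworkConfig",
    "TrainedNetwork",
    "CVReport",
    "train_network",
    "predict",
    "cross_validate",
    "grid_configs",
    "save_network",
    "load_network",
]

HIDDEN_GRID: tuple[tuple[int, ...], ...] = ((512,), (512, 128), (512, 128, 8))
OPTIMIZERS: tuple[str, ...] = ("Adamax", "Adam")


@dataclass(frozen=True)
class NetworkConfig:
    hidden_sizes: tuple[int, ...] = (512, 128, 8)
    optimizer: str = "Adamax"
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= len(self.hidden_sizes) <= 3:
            raise ValueError("hidden layer count must be 1, 2 or 3")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"optimizer must be one of {OPTIMIZERS}")


@dataclass
class TrainedNetwork:
    """Weights plus provenance; guarantees probability outputs in [0, 1]."""

    config: NetworkConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    feature_family: str = ""
    n_features: int = 0

    def predict_proba(self, X) -> np.ndarray:
        X = _check_width(np.asarray(X, dtype=float), self.n_features)
        a = X
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            a = _sigmoid(z) if i == last else np.maximum(z, 0.0)
        return a.ravel()


@dataclass
class CVReport:
    per_fold: list[MetricSet]
    k: int

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")

    @property
    def mean_sd(self) -> dict[str, tuple[float, float]]:
        keys = self.per_fold[0].as_dict().keys()
        out = {}
        for key in keys:
            vals = np.array([m.as_dict()[key] for m in self.per_fold])
            out[key] = (float(vals.mean()), float(vals.std(ddof=1)))
        return out

    def mean(self, key: str) -> float:
        return self.mean_sd[key][0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "per_fold": [m.as_dict() for m in self.per_fold],
                "mean_sd": {k: list(v) for k, v in self.mean_sd.items()},
            },
            indent=2,
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _check_width(X: np.ndarray, p: int) -> np.ndarray:
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != p:
        raise ValueError(f"input width {X.shape[1]} does not match n_features {p}")
    return X


class _Optimizer:
    """Adam / Adamax updates (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, kind: str, params: list[np.ndarray], lr: float):
        self.kind = kind
        self.lr = lr
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            if self.kind == "Adam":
                v *= b2
                v += (1 - b2) * g * g
                mhat = m / (1 - b1**self.t)
                vhat = v / (1 - b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + eps)
            else:  # Adamax: infinity-norm second moment
                np.maximum(b2 * v, np.abs(g), out=v)
                p -= (self.lr / (1 - b1**self.t)) * m / (v + eps)


def _extract(X):
    """Accept a FeatureMatrix or a plain array."""
    if hasattr(X, "values") and hasattr(X, "family"):
        return np.asarray(X.values, dtype=float), X.family.name
    return np.asarray(X, dtype=float), ""


def train_network(X, y, cfg: NetworkConfig) -> TrainedNetwork:
    """Fit the network on binary labels with mini-batch gradient descent.

    Deterministic for a fixed config seed: weight initialization (He for
    hidden layers, Glorot for the output) and epoch shuffling both draw
    from one seeded generator.
    """
    Xv, family = _extract(X)
    y = np.asarray(y, dtype=float).ravel()
    if Xv.shape[0] != y.shape[0]:
        raise ValueError("X rows and y length differ")
    classes = set(np.unique(y).tolist())
    if not classes <= {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if len(classes) < 2:
        raise ValueError("y contains a single class; nothing to learn")

    rng = np.random.default_rng(cfg.seed)
    sizes = [Xv.shape[1], *cfg.hidden_sizes, 1]
    weights, biases = [], []
    for i, (fan_in, fan_out) in enumerate(zip(sizes[:-1], sizes[1:])):
        if i < len(sizes) - 2:  # He initialization for ReLU layers
            scale = np.sqrt(2.0 / fan_in)
        else:  # Glorot for the sigmoid output
            scale = np.sqrt(1.0 / fan_in)
        weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))

    params = weights + biases
    opt = _Optimizer(cfg.optimizer, params, cfg.learning_rate)
    n = Xv.shape[0]
    n_layers = len(weights)

    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = Xv[idx], y[idx]
            # forward
            acts = [xb]
            for i, (W, b) in enumerate(zip(weights, biases)):
                z = acts[-1] @ W + b
                acts.append(_sigmoid(z) if i == n_layers - 1 else np.maximum(z, 0.0))
            # backward; dL/dz at the output simplifies to (p - y)/m for
            # sigmoid + binary cross-entropy
            m = len(idx)
            delta = (acts[-1].ravel() - yb)[:, None] / m
            grads_w = [None] * n_layers
            grads_b = [None] * n_layers
            for i in range(n_layers - 1, -1, -1):
                grads_w[i] = acts[i].T @ delta
                grads_b[i] = delta.sum(axis=0)
                if i > 0:
                    delta = (delta @ weights[i].T) * (acts[i] > 0)
            opt.step(params, grads_w + grads_b)

    return TrainedNetwork(
        config=cfg,
        weights=weights,
        biases=biases,
        feature_family=family,
        n_features=Xv.shape[1],
    )


def predict(net: TrainedNetwork, X, threshold: float = 0.5):
    """Return (probabilities, hard labels); label 1 iff p >= threshold."""
    proba = net.predict_proba(_extract(X)[0])
    return proba, (proba >= threshold).astype(int)


def cross_validate(
    X, y, cfg: NetworkConfig, k: int = 10, seed: int = 0
) -> CVReport:
    """Stratified k-fold cross-validation reporting all six scores."""
    from sklearn.model_selection import StratifiedKFold

    Xv, _ = _extract(X)
    y = np.asarray(y, dtype=int).ravel()
    if Xv.shape[0] < k:
        raise ValueError("need at least k samples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold = []
    for fold, (tr, te) in enumerate(skf.split(Xv, y)):
        fold_cfg = NetworkConfig(**{**asdict(cfg), "seed": (cfg.seed + fold) % 2**31})
        net = train_network(Xv[tr], y[tr], fold_cfg)
        _, labels = predict(net, Xv[te])
        per_fold.append(compute_metrics(confusion_counts(y[te], labels)))
    return CVReport(per_fold=per_fold, k=k)


def save_network(net: TrainedNetwork, path) -> None:
    """Single-file parameter archive with a JSON header (family, config)."""
    header = {
        "config": asdict(net.config),
        "feature_family": net.feature_family,
        "n_features": net.n_features,
        "n_layers": len(net.weights),
    }
    arrays = {f"W{i}": w for i, w in enumerate(net.weights)}
    arrays |= {f"b{i}": b for i, b in enumerate(net.biases)}
    np.savez(path, header=json.dumps(header), **arrays)


def load_network(path) -> TrainedNetwork:
    with np.load(path, allow_pickle=False) as archive:
        header = json.loads(str(archive["header"]))
        cfg_dict = header["config"]
        cfg_dict["hidden_sizes"] = tuple(cfg_dict["hidden_sizes"])
        n_layers = header["n_layers"]
        return TrainedNetwork(
            config=NetworkConfig(**cfg_dict),
            weights=[archive[f"W{i}"] for i in range(n_layers)],
            biases=[archive[f"b{i}"] for i in range(n_layers)],
            feature_family=header["feature_family"],
            n_features=header["n_features"],
        )


def grid_configs(
    families: list[str],
    hidden_grid: tuple[tuple[int, ...], ...] = HIDDEN_GRID,
    optimizers: tuple[str, ...] = OPTIMIZERS,
    **kwargs,
) -> list[tuple[str, NetworkConfig]]:
    """Cross product families x depth options x optimizers.

    13 feature families with the full grid give 78 single-model
    configurations; fixing depth and optimizer gives one per family.
    """
    if not families:
        raise ValueError("family list is empty")
    if len(set(families)) != len(families):
        raise ValueError("duplicate family names")
    return [
        (fam, NetworkConfig(hidden_sizes=h, optimizer=opt, **kwargs))
        for fam, h, opt in itertools.product(families, hidden_grid, optimizers)
    ]
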