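"""The two neural sentence classifiers: a three-layer MLP and an RBF network.

Both consume 512-dimensional sentence embeddings and emit seven per-domain
scores through independent output nodes (no softmax normalization), which
is what makes open-world, multilabel prediction possible downstream.

MLP
    512 inputs (dropout 0.2) -> 250 ReLU units (dropout 0.5) -> 7 sigmoid
    outputs; Adam, categorical cross entropy, 60 epochs, batch 128.

RBF
    512 inputs (dropout 0.2) -> 700 Gaussian units -> 7 linear outputs;
    Adam, mean squared error, 50 epochs, batch 128.  The 700 hidden
    prototypes are fixed before training: k-means centroids (100 per
    domain) computed on each domain megadocument individually.  Every
    hidden unit shares one width derived from the maximum pairwise
    Euclidean distance between prototypes (see :func:`compute_width` for
    the rules); only the linear output layer is fit by gradient descent.

The networks are implemented directly on numpy with seeded Glorot-uniform
initialization, inverted dropout and Adam at its standard defaults
(lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8), so training is bit-for-bit
reproducible for a fixed seed.  The categorical cross entropy follows the
deep-learning-framework convention for probability inputs: predictions are
renormalized to sum to one inside the loss (the model's outputs themselves
stay unnormalized sigmoids).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .baseline import DomainScores
from .corpus import Megadocument
from .domains import DomainLabel, RISK_DOMAINS

_EPS = 1e-7  # probability clip inside the cross entropy


# ------------------------------------------------------------------ configs
@dataclass(frozen=True)
class MlpConfig:
    input_nodes: int = 512
    input_dropout: float = 0.2
    hidden_nodes: int = 250
    hidden_dropout: float = 0.5
    output_nodes: int = 7
    epochs: int = 60
    batch_size: int = 128
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.input_nodes, self.hidden_nodes, self.output_nodes,
               self.epochs, self.batch_size) <= 0:
            raise ValueError("all counts must be positive")
        for rate in (self.input_dropout, self.hidden_dropout):
            if not 0.0 <= rate < 1.0:
                raise ValueError("dropout must lie in [0, 1)")


@dataclass(frozen=True)
class RbfConfig:
    input_nodes: int = 512
    input_dropout: float = 0.2
    prototypes_per_domain: int = 100
    output_nodes: int = 7
    epochs: int = 50
    batch_size: int = 128
    learning_rate: float = 1e-3
    width_rule: str = "dmax_sqrt2c"  # or "dmax_sqrt2m", "dmax", "custom"
    custom_width: float | None = None
    seed: int = 0

    @property
    def hidden_nodes(self) -> int:
        return self.prototypes_per_domain * self.output_nodes

    def __post_init__(self) -> None:
        if min(self.input_nodes, self.prototypes_per_domain, self.output_nodes,
               self.epochs, self.batch_size) <= 0:
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.input_dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.width_rule not in ("dmax_sqrt2c", "dmax_sqrt2m", "dmax", "custom"):
            raise ValueError(f"unknown width rule: {self.width_rule!r}")
        if self.width_rule == "custom" and not (self.custom_width and self.custom_width > 0):
            raise ValueError("custom width rule requires a positive custom_width")


@dataclass
class TrainedModel:
    """A fitted classifier with its label order and opaque weight store."""

    kind: str  # "mlp" | "rbf"
    config: MlpConfig | RbfConfig
    params: dict[str, np.ndarray]
    label_order: tuple[DomainLabel, ...] = RISK_DOMAINS
    history: list[float] = field(default_factory=list)  # per-epoch training loss

    def score_matrix(self, X: np.ndarray) -> np.ndarray:
        """Per-domain scores, one row per input sentence.

        MLP scores are sigmoids in (0,1); RBF scores are unbounded reals
        (linear output).  Scores are independent per domain — they need not
        sum to one.
        """
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.config.input_nodes:
            raise ValueError(
                f"input dimension {X.shape[1]} != model input {self.config.input_nodes}"
            )
        if self.kind == "mlp":
            h = np.maximum(X @ self.params["W1"] + self.params["b1"], 0.0)
            z = h @ self.params["W2"] + self.params["b2"]
            return _sigmoid(z)
        phi = rbf_hidden(X, self.params["prototypes"], float(self.params["width"][0]))
        return phi @ self.params["W"] + self.params["b"]

    def score(self, v: np.ndarray, sentence_id: str = "") -> DomainScores:
        row = self.score_matrix(np.asarray(v)[None, :])[0]
        return DomainScores(sentence_id, dict(zip(self.label_order, row.tolist())))

    def n_parameters(self) -> int:
        """Trainable parameter count (prototypes and width are fixed)."""
        trainable = {"W1", "b1", "W2", "b2", "W", "b"}
        return sum(p.size for k, p in self.params.items() if k in trainable)


# ------------------------------------------------------------------- helpers
def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class _Adam:
    def __init__(self, shapes: Mapping[str, tuple[int, ...]], lr: float) -> None:
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}

    def step(self, params: dict[str, np.ndarray], grads: Mapping[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


def _dropout(rng: np.random.Generator, x: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = rng.random(x.shape) < keep
    return x * mask / keep


def one_hot(labels: Sequence[DomainLabel], order: Sequence[DomainLabel] = RISK_DOMAINS) -> np.ndarray:
    """One-hot matrix over the canonical domain order (single-label training)."""
    index = {d: i for i, d in enumerate(order)}
    Y = np.zeros((len(labels), len(order)), dtype=np.float64)
    for i, lab in enumerate(labels):
        Y[i, index[lab]] = 1.0
    return Y


def _check_xy(X: np.ndarray, Y: np.ndarray, input_nodes: int, output_nodes: int) -> None:
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if X.shape[0] != Y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but Y has {Y.shape[0]}")
    if X.shape[1] != input_nodes:
        raise ValueError(f"X dimension {X.shape[1]} != input_nodes {input_nodes}")
    if Y.shape[1] != output_nodes:
        raise ValueError(f"Y width {Y.shape[1]} != output_nodes {output_nodes}")


def _cce(Y: np.ndarray, P: np.ndarray) -> float:
    Pn = P / np.clip(P.sum(axis=1, keepdims=True), _EPS, None)
    Pn = np.clip(Pn, _EPS, 1.0 - _EPS)
    return float(-(Y * np.log(Pn)).sum(axis=1).mean())


# ----------------------------------------------------------------- training
def train_mlp(X: np.ndarray, Y: np.ndarray, config: MlpConfig = MlpConfig()) -> TrainedModel:
    """Fit the three-layer MLP on one-hot single-label training data."""
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    _check_xy(X, Y, config.input_nodes, config.output_nodes)
    rng = np.random.Generator(np.random.PCG64(config.seed))
    params = {
        "W1": _glorot(rng, config.input_nodes, config.hidden_nodes),
        "b1": np.zeros(config.hidden_nodes),
        "W2": _glorot(rng, config.hidden_nodes, config.output_nodes),
        "b2": np.zeros(config.output_nodes),
    }
    opt = _Adam({k: v.shape for k, v in params.items()}, config.learning_rate)
    n = X.shape[0]
    history: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X[idx], Y[idx]
            x0 = _dropout(rng, xb, config.input_dropout)
            a1 = x0 @ params["W1"] + params["b1"]
            h = np.maximum(a1, 0.0)
            if config.hidden_dropout > 0:
                keep = 1.0 - config.hidden_dropout
                mask_h = (rng.random(h.shape) < keep) / keep
            else:
                mask_h = 1.0
            hd = h * mask_h
            z = hd @ params["W2"] + params["b2"]
            p = _sigmoid(z)
            epoch_loss += _cce(yb, p) * len(idx)

            # d(cce)/dp with in-loss renormalization, then through the sigmoid
            s = np.clip(p.sum(axis=1, keepdims=True), _EPS, None)
            dp = (-yb / np.clip(p, _EPS, None) + yb.sum(axis=1, keepdims=True) / s) / len(idx)
            dz = dp * p * (1.0 - p)
            grads = {
                "W2": hd.T @ dz,
                "b2": dz.sum(axis=0),
            }
            dh = (dz @ params["W2"].T) * mask_h * (a1 > 0)
            grads["W1"] = x0.T @ dh
            grads["b1"] = dh.sum(axis=0)
            opt.step(params, grads)
        history.append(epoch_loss / n)
    return TrainedModel(kind="mlp", config=config, params=params, history=history)


def select_prototypes(
    megadocs: Sequence[Megadocument],
    vectors: Mapping[str, np.ndarray],
    k_per_domain: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """k-means centroids per domain megadocument, stacked into ``(7k, d)``.

    k-means++ seeding with 10 restarts, best inertia; deterministic for a
    fixed seed.  Raises when a megadocument holds fewer sentences than
    ``k_per_domain`` (naming the offending domain).
    """
    if k_per_domain < 1:
        raise ValueError("k_per_domain must be >= 1")
    blocks: list[np.ndarray] = []
    for md in megadocs:
        if len(md.sentences) < k_per_domain:
            raise ValueError(
                f"domain {md.domain.value} has {len(md.sentences)} sentences "
                f"< k_per_domain={k_per_domain}"
            )
        mat = np.stack([vectors[s.id] for s in md.sentences]).astype(np.float64)
        km = KMeans(n_clusters=k_per_domain, n_init=10, random_state=seed)
        km.fit(mat)
        blocks.append(km.cluster_centers_)
    return np.vstack(blocks)


def compute_width(
    prototypes: np.ndarray,
    rule: str = "dmax_sqrt2m",
    custom: float | None = None,
    n_classes: int = 7,
) -> float:
    """Shared Gaussian width from the maximum pairwise prototype distance.

    Rules, all based off ``d_max`` (the maximum pairwise Euclidean distance
    between prototype centroids):

    ``dmax_sqrt2m``
        The classical heuristic sigma = d_max / sqrt(2 m), with m the
        number of prototypes.  Appropriate when the m centers tile the
        input space; with many overlapping per-domain prototypes it can
        collapse the kernel to near-zero support.
    ``dmax_sqrt2c``
        The same normalization applied at the level of the well-separated
        clusters actually present — the ``n_classes`` domains:
        sigma = d_max / sqrt(2 c).
    ``dmax``
        sigma = d_max.
    ``custom``
        A user-supplied positive width.
    """
    prototypes = np.asarray(prototypes, dtype=np.float64)
    if rule == "custom":
        if custom is None or custom <= 0:
            raise ValueError("custom width must be positive")
        return float(custom)
    m = prototypes.shape[0]
    if m < 2:
        raise ValueError("need at least 2 prototypes")
    d_max = float(pdist(prototypes).max())
    if d_max == 0.0:
        raise ValueError("all prototypes identical; width undefined")
    if rule == "dmax":
        return d_max
    if rule == "dmax_sqrt2m":
        return d_max / np.sqrt(2.0 * m)
    if rule == "dmax_sqrt2c":
        return d_max / np.sqrt(2.0 * n_classes)
    raise ValueError(f"unknown width rule: {rule!r}")


def rbf_hidden(X: np.ndarray, prototypes: np.ndarray, width: float) -> np.ndarray:
    """Gaussian activations exp(-||x - p||^2 / (2 sigma^2)), each in (0, 1]."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    sq = (
        np.sum(X * X, axis=1)[:, None]
        + np.sum(prototypes * prototypes, axis=1)[None, :]
        - 2.0 * X @ prototypes.T
    )
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-sq / (2.0 * width * width))


def train_rbf(
    X: np.ndarray,
    Y: np.ndarray,
    config: RbfConfig,
    prototypes: np.ndarray,
    width: float | None = None,
) -> TrainedModel:
    """Fit the RBF network's linear output layer; prototypes stay fixed."""
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    _check_xy(X, Y, config.input_nodes, config.output_nodes)
    prototypes = np.asarray(prototypes, dtype=np.float64)
    if prototypes.shape != (config.hidden_nodes, config.input_nodes):
        raise ValueError(
            f"prototypes shape {prototypes.shape} != {(config.hidden_nodes, config.input_nodes)}"
        )
    if width is None:
        width = compute_width(
            prototypes, config.width_rule, config.custom_width, config.output_nodes
        )
    if width <= 0:
        raise ValueError("width must be positive")
    rng = np.random.Generator(np.random.PCG64(config.seed))
    params = {
        "W": _glorot(rng, config.hidden_nodes, config.output_nodes),
        "b": np.zeros(config.output_nodes),
    }
    opt = _Adam({k: v.shape for k, v in params.items()}, config.learning_rate)
    n = X.shape[0]
    history: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X[idx], Y[idx]
            x0 = _dropout(rng, xb, config.input_dropout)
            phi = rbf_hidden(x0, prototypes, width)
            out = phi @ params["W"] + params["b"]
            diff = out - yb
            epoch_loss += float((diff * diff).mean()) * len(idx)
            dout = 2.0 * diff / diff.size
            opt.step(params, {"W": phi.T @ dout, "b": dout.sum(axis=0)})
        history.append(epoch_loss / n)
    params["prototypes"] = prototypes
    params["width"] = np.array([width])
    return TrainedModel(kind="rbf", config=config, params=params, history=history)


# ------------------------------------------------------------- persistence
def save_model(model: TrainedModel, directory) -> None:
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz", **model.params)
    cfg = {k: v for k, v in vars(model.config).items()}
    with open(directory / "config.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "kind": model.kind,
                "config": cfg,
                "label_order": [d.value for d in model.label_order],
                "history": model.history,
            },
            fh,
            indent=2,
        )


def load_model(directory) -> TrainedModel:
    import json
    from pathlib import Path

    from .domains import parse_label

    directory = Path(directory)
    with open(directory / "config.json", encoding="utf-8") as fh:
        meta = json.load(fh)
    config_cls = MlpConfig if meta["kind"] == "mlp" else RbfConfig
    config = config_cls(**meta["config"])
    with np.load(directory / "weights.npz") as npz:
        params = {k: npz[k] for k in npz.files}
    return TrainedModel(
        kind=meta["kind"],
        config=config,
        params=params,
        label_order=tuple(parse_label(d) for d in meta["label_order"]),
        history=list(meta.get("history", [])),
    )
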