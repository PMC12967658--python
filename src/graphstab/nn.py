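"""The graph classifier: attention conv → neighborhood aggregation →
self-attention pooling → global add pooling → dense head → logit.

Implemented directly on NumPy + scipy.sparse with hand-derived backprop
(gradient-checked in the test suite against central finite differences).

Layer semantics follow the common graph-learning conventions:

* **Attention conv** (GAT-style, single head): node i aggregates its
  in-neighborhood (self-loop included) with softmax attention over
  ``LeakyReLU(a_src·Wh_j + a_dst·Wh_i + a_dist·d_ij)``, where ``d_ij`` is the
  Cα–Cα edge distance (0 on the self-loop) — this is how the per-edge
  distance annotation enters the model.
* **Neighborhood aggregation** (GraphSAGE-style, mean aggregator):
  ``W_self·h_i + W_neigh·mean_{j∈N(i)} h_j``.
* **Self-attention pooling** (SAGPool): a one-dimensional graph-conv score
  per node; the top ``ceil(ratio·n)`` nodes of each graph are kept and their
  features gated by ``tanh(score)``.
* **Global add pooling** sums the surviving node embeddings per graph; two
  dense layers map the graph vector to a single logit; ``sigmoid`` gives the
  probability of the active class.

Training minimizes binary cross-entropy with Adam; the stated L2 penalty is
applied as Adam weight decay.  Early stopping monitors an inner stratified
validation split (never the test fold) and restores the best weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from ._batching import GraphBatch, _DigestedGraph, digest_graph
from .graphs import ProteinGraph

_DTYPE = np.float32
_NEG_SLOPE = 0.2  # LeakyReLU slope in attention scoring


@dataclass
class ModelConfig:
    """Architecture + training hyperparameters.

    Defaults follow the published training setup: 128 hidden units in every
    network layer, dropout 0.2, learning rate 1e-5, L2 regularization 1e-3
    and early-stopping patience of 50 epochs.  ``max_epochs``, ``batch_size``
    and ``pooling_ratio`` are desk-scale choices (see docs/methods.md).
    """

    hidden_units: int = 128
    dropout: float = 0.2
    learning_rate: float = 1e-5
    l2_weight: float = 1e-3
    patience: int = 50
    max_epochs: int = 100
    pooling_ratio: float = 0.8
    batch_size: int = 16
    seed: int = 0
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not (0 <= self.dropout < 1):
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        if not (0 < self.pooling_ratio <= 1):
            raise ValueError(f"pooling_ratio must be in (0, 1], got {self.pooling_ratio}")
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be positive")
        if self.patience > self.max_epochs:
            raise ValueError(
                f"patience ({self.patience}) must not exceed max_epochs ({self.max_epochs})"
            )
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 < self.val_fraction < 0.5):
            raise ValueError("val_fraction must be in (0, 0.5)")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(_DTYPE)


def init_params(config: ModelConfig, seed: Optional[int] = None) -> dict[str, np.ndarray]:
    """Seeded Glorot-uniform initialization of all trainable arrays."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    h = config.hidden_units
    h2 = max(1, h // 2)
    p = {
        "gat.W": _glorot(rng, 6, h, (6, h)),
        "gat.a_src": _glorot(rng, 1, h, (h,)),
        "gat.a_dst": _glorot(rng, 1, h, (h,)),
        "gat.a_dist": np.zeros(1, dtype=_DTYPE),
        "gat.b": np.zeros(h, dtype=_DTYPE),
        "sage.W_self": _glorot(rng, h, h, (h, h)),
        "sage.W_neigh": _glorot(rng, h, h, (h, h)),
        "sage.b": np.zeros(h, dtype=_DTYPE),
        "pool.w_self": _glorot(rng, h, 1, (h,)),
        "pool.w_neigh": _glorot(rng, h, 1, (h,)),
        "pool.b": np.zeros(1, dtype=_DTYPE),
        "fc1.W": _glorot(rng, h, h2, (h, h2)),
        "fc1.b": np.zeros(h2, dtype=_DTYPE),
        "fc2.W": _glorot(rng, h2, 1, (h2, 1)),
        "fc2.b": np.zeros(1, dtype=_DTYPE),
    }
    return p


@dataclass
class GNNModel:
    """An (untrained) model: parameter arrays plus their configuration."""

    config: ModelConfig
    params: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.params:
            self.params = init_params(self.config)


def init_model(config: ModelConfig, seed: Optional[int] = None) -> GNNModel:
    """Build an untrained model with seed-reproducible initial weights."""
    return GNNModel(config=config, params=init_params(config, seed))


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------


def _topk_per_graph(scores: np.ndarray, node_ptr: np.ndarray, ratio: float) -> np.ndarray:
    """Indices (ascending) of the top ceil(ratio*n) scoring nodes per graph.

    Ties broken toward the lower node index (stable sort on -score).
    """
    keep = []
    for g in range(len(node_ptr) - 1):
        lo, hi = node_ptr[g], node_ptr[g + 1]
        n = hi - lo
        k = int(np.ceil(ratio * n))
        seg = scores[lo:hi]
        order = np.argsort(-seg, kind="stable")[:k]
        keep.append(np.sort(order) + lo)
    return np.concatenate(keep)


def _forward(
    params: dict[str, np.ndarray],
    batch: GraphBatch,
    config: ModelConfig,
    training: bool = False,
    rng: Optional[np.random.Generator] = None,
):
    """Forward pass; returns (logits, cache) — cache feeds :func:`_backward`."""
    x = batch.x
    if x.shape[1] != params["gat.W"].shape[0]:
        raise ValueError(
            f"feature dimension {x.shape[1]} != model input dimension "
            f"{params['gat.W'].shape[0]}"
        )
    cache: dict = {"training": training}

    # --- attention conv -----------------------------------------------------
    h0 = x @ params["gat.W"]                       # (N, H)
    es = h0 @ params["gat.a_src"]                  # (N,)
    ed = h0 @ params["gat.a_dst"]
    pre = es[batch.sl_src] + ed[batch.sl_dst] + params["gat.a_dist"][0] * batch.sl_dist
    leak = np.where(pre > 0, 1.0, _NEG_SLOPE).astype(_DTYPE)
    e = pre * leak
    alpha = batch.segment_softmax(e)
    A = batch.attention_csr(alpha)
    g1 = A @ h0 + params["gat.b"]
    z1 = np.where(g1 > 0, g1, np.expm1(g1))        # ELU
    cache.update(h0=h0, leak=leak, alpha=alpha, A=A, g1=g1, z1_pre_drop=z1)

    if training and config.dropout > 0:
        m1 = (rng.random(z1.shape, dtype=np.float32) >= config.dropout).astype(_DTYPE)
        m1 *= 1.0 / (1.0 - config.dropout)
        z1 = z1 * m1
        cache["m1"] = m1
    cache["z1"] = z1

    # --- neighborhood aggregation -------------------------------------------
    mean_nb = batch.A_mean @ z1
    z2 = z1 @ params["sage.W_self"] + mean_nb @ params["sage.W_neigh"] + params["sage.b"]
    a2 = np.maximum(z2, 0)
    cache.update(mean_nb=mean_nb, z2=z2, a2_pre_drop=a2)

    if training and config.dropout > 0:
        m2 = (rng.random(a2.shape, dtype=np.float32) >= config.dropout).astype(_DTYPE)
        m2 *= 1.0 / (1.0 - config.dropout)
        a2 = a2 * m2
        cache["m2"] = m2
    cache["a2"] = a2

    # --- self-attention pooling + global add pooling ------------------------
    sum_nb = batch.A_sum @ a2
    s = a2 @ params["pool.w_self"] + sum_nb @ params["pool.w_neigh"] + params["pool.b"][0]
    keep = _topk_per_graph(s, batch.node_ptr, config.pooling_ratio)
    t = np.tanh(s[keep])
    y = a2[keep] * t[:, None]
    kept_graph = batch.node_graph[keep]
    pooled = batch.graph_sum(y, kept_graph)
    cache.update(sum_nb=sum_nb, s=s, keep=keep, t=t, kept_graph=kept_graph)

    # --- dense head ----------------------------------------------------------
    p1 = pooled @ params["fc1.W"] + params["fc1.b"]
    r1 = np.maximum(p1, 0)
    cache.update(pooled=pooled, p1=p1, r1_pre_drop=r1)
    if training and config.dropout > 0:
        m3 = (rng.random(r1.shape, dtype=np.float32) >= config.dropout).astype(_DTYPE)
        m3 *= 1.0 / (1.0 - config.dropout)
        r1 = r1 * m3
        cache["m3"] = m3
    cache["r1"] = r1
    logits = (r1 @ params["fc2.W"] + params["fc2.b"])[:, 0]
    return logits, cache


def _backward(
    params: dict[str, np.ndarray],
    batch: GraphBatch,
    cache: dict,
    grad_logits: np.ndarray,
) -> dict[str, np.ndarray]:
    """Gradients of the scalar loss w.r.t. every parameter array."""
    grads: dict[str, np.ndarray] = {}
    gl = grad_logits[:, None].astype(_DTYPE)        # (G, 1)

    # dense head
    r1 = cache["r1"]
    grads["fc2.W"] = r1.T @ gl
    grads["fc2.b"] = gl.sum(axis=0)
    gr1 = gl @ params["fc2.W"].T
    if "m3" in cache:
        gr1 = gr1 * cache["m3"]
    gp1 = gr1 * (cache["p1"] > 0)
    grads["fc1.W"] = cache["pooled"].T @ gp1
    grads["fc1.b"] = gp1.sum(axis=0)
    gpooled = gp1 @ params["fc1.W"].T               # (G, H)

    # global add pooling -> kept nodes
    keep, t, kept_graph = cache["keep"], cache["t"], cache["kept_graph"]
    gy = gpooled[kept_graph]                        # (K, H)
    a2 = cache["a2"]
    ga2 = np.zeros_like(a2)
    ga2[keep] = gy * t[:, None]
    gt = (gy * a2[keep]).sum(axis=1)
    gs = np.zeros(a2.shape[0], dtype=_DTYPE)
    gs[keep] = gt * (1.0 - t * t)

    # pooling score s = a2 @ w_self + (A_sum @ a2) @ w_neigh + b
    grads["pool.w_self"] = a2.T @ gs
    grads["pool.w_neigh"] = cache["sum_nb"].T @ gs
    grads["pool.b"] = np.array([gs.sum()], dtype=_DTYPE)
    ga2 = ga2 + gs[:, None] * params["pool.w_self"][None, :]
    ga2 += batch.A_sum.T @ (gs[:, None] * params["pool.w_neigh"][None, :])

    # neighborhood aggregation
    if "m2" in cache:
        ga2 = ga2 * cache["m2"]
    gz2 = ga2 * (cache["z2"] > 0)
    z1 = cache["z1"]
    grads["sage.W_self"] = z1.T @ gz2
    grads["sage.W_neigh"] = cache["mean_nb"].T @ gz2
    grads["sage.b"] = gz2.sum(axis=0)
    gz1 = gz2 @ params["sage.W_self"].T
    gz1 += batch.A_mean.T @ (gz2 @ params["sage.W_neigh"].T)

    # attention conv
    if "m1" in cache:
        gz1 = gz1 * cache["m1"]
    g1 = cache["g1"]
    elu_grad = np.where(g1 > 0, _DTYPE(1.0), cache["z1_pre_drop"] + _DTYPE(1.0))
    gg1 = gz1 * elu_grad  # ELU'(x) = 1 for x > 0, elu(x) + 1 otherwise
    grads["gat.b"] = gg1.sum(axis=0)
    A, alpha, h0, leak = cache["A"], cache["alpha"], cache["h0"], cache["leak"]
    gh0 = A.T @ gg1                                  # via aggregated sources
    galpha = (gg1[batch.sl_dst] * h0[batch.sl_src]).sum(axis=1)
    # softmax backward per destination segment
    starts = batch.sl_indptr[:-1]
    dot = np.add.reduceat(alpha * galpha, starts)
    ge = alpha * (galpha - dot[batch.sl_dst])
    gpre = ge * leak
    ges = np.bincount(batch.sl_src, weights=gpre, minlength=h0.shape[0]).astype(_DTYPE)
    ged = np.bincount(batch.sl_dst, weights=gpre, minlength=h0.shape[0]).astype(_DTYPE)
    grads["gat.a_dist"] = np.array([(gpre * batch.sl_dist).sum()], dtype=_DTYPE)
    grads["gat.a_src"] = h0.T @ ges
    grads["gat.a_dst"] = h0.T @ ged
    gh0 += ges[:, None] * params["gat.a_src"][None, :]
    gh0 += ged[:, None] * params["gat.a_dst"][None, :]
    grads["gat.W"] = batch.x.T @ gh0
    return grads


def bce_with_logits(logits: np.ndarray, y: np.ndarray):
    """Mean binary cross-entropy on logits; returns (loss, grad_logits)."""
    z = logits.astype(np.float64)
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    grad = (1.0 / (1.0 + np.exp(-z)) - y) / len(z)
    return float(loss), grad


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float, weight_decay: float):
        self.lr = lr
        self.wd = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, p in params.items():
            g = grads[k] + self.wd * p  # L2 regularization
            m = self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            v = self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    """Fitted weights plus the training record."""

    config: ModelConfig
    params: dict[str, np.ndarray]
    train_losses: list[float]
    val_losses: list[float]
    best_epoch: int      # 1-based epoch whose weights are kept
    stopped_epoch: int   # 1-based last epoch run

    def predict_proba(self, graphs: Sequence[ProteinGraph]) -> np.ndarray:
        return predict_proba(self, graphs)

    def save(self, path) -> None:
        """Checkpoint: config JSON + weight arrays in one .npz file."""
        arrays = dict(self.params)
        meta = {
            "config": asdict(self.config),
            "train_losses": self.train_losses,
            "val_losses": self.val_losses,
            "best_epoch": self.best_epoch,
            "stopped_epoch": self.stopped_epoch,
        }
        arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        params = {k: data[k] for k in data.files if k != "__meta__"}
        return cls(
            config=ModelConfig(**meta["config"]),
            params=params,
            train_losses=meta["train_losses"],
            val_losses=meta["val_losses"],
            best_epoch=meta["best_epoch"],
            stopped_epoch=meta["stopped_epoch"],
        )

    def write_training_log(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "train_loss", "val_loss"])
            for i, (tl, vl) in enumerate(zip(self.train_losses, self.val_losses), 1):
                w.writerow([i, f"{tl:.6f}", f"{vl:.6f}"])


def _stratified_val_split(labels: np.ndarray, frac: float, rng: np.random.Generator):
    """Inner validation split for early stopping (never touches test folds)."""
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(frac * len(idx)))) if len(idx) >= 2 else 0
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(np.array(train_idx)), np.sort(np.array(val_idx))


def train(
    model: GNNModel,
    graphs: Sequence[ProteinGraph],
    labels: Sequence[int],
    digested: Optional[list[_DigestedGraph]] = None,
) -> TrainedModel:
    """Train with minibatch Adam, early-stopping on an inner validation split.

    Stops when the validation loss has not improved for ``patience``
    consecutive epochs (or at ``max_epochs``); the best-validation weights
    are restored.  Fully reproducible from ``config.seed``.
    """
    config = model.config
    y = np.asarray(labels, dtype=np.float64)
    if len(graphs) != len(y):
        raise ValueError("graphs and labels differ in length")
    if len(y) < 2 or len(np.unique(y)) < 2:
        raise ValueError("training requires at least 2 graphs with both classes present")

    if digested is None:
        digested = [digest_graph(g) for g in graphs]
    rng = np.random.default_rng(config.seed)
    params = {k: v.copy() for k, v in model.params.items()}
    opt = _Adam(params, config.learning_rate, config.l2_weight)

    tr_idx, va_idx = _stratified_val_split(y, config.val_fraction, rng)
    if len(va_idx) == 0:  # degenerate tiny set: monitor training data instead
        va_idx = tr_idx
    val_batch = GraphBatch([digested[i] for i in va_idx])
    y_val = y[va_idx]

    best_val = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    best_epoch = 0
    bad_epochs = 0
    train_losses, val_losses = [], []
    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(tr_idx)
        epoch_loss, n_seen = 0.0, 0
        for lo in range(0, len(order), config.batch_size):
            bidx = order[lo : lo + config.batch_size]
            batch = GraphBatch([digested[i] for i in bidx])
            logits, cache = _forward(params, batch, config, training=True, rng=rng)
            loss, grad_logits = bce_with_logits(logits, y[bidx])
            grads = _backward(params, batch, cache, grad_logits)
            opt.step(params, grads)
            epoch_loss += loss * len(bidx)
            n_seen += len(bidx)
        train_losses.append(epoch_loss / n_seen)

        logits_val, _ = _forward(params, val_batch, config, training=False)
        val_loss, _ = bce_with_logits(logits_val, y_val)
        val_losses.append(val_loss)

        if val_loss < best_val:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in params.items()}
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break

    return TrainedModel(
        config=config,
        params=best_params,
        train_losses=train_losses,
        val_losses=val_losses,
        best_epoch=best_epoch,
        stopped_epoch=epoch,
    )


def predict_proba(
    model: TrainedModel | GNNModel,
    graphs: Sequence[ProteinGraph],
    batch_size: int = 256,
) -> np.ndarray:
    """Probability of the active class per graph (evaluation mode, batched).

    Batch composition does not affect the outputs.
    """
    digested = [digest_graph(g) for g in graphs]
    out = np.empty(len(graphs), dtype=np.float64)
    for lo in range(0, len(digested), batch_size):
        chunk = digested[lo : lo + batch_size]
        batch = GraphBatch(chunk)
        logits, _ = _forward(model.params, batch, model.config, training=False)
        out[lo : lo + len(chunk)] = 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))
    return out


# ---------------------------------------------------------------------------
# scikit-learn style estimator
# ---------------------------------------------------------------------------


class GraphStabilityClassifier:
    """Binary classifier of protein variants on residue contact graphs.

    A scikit-learn-style estimator: ``fit(graphs, y)`` trains the network,
    ``predict_proba`` / ``predict`` score new graphs.  ``X`` is a sequence of
    :class:`~graphstab.graphs.ProteinGraph` built with the package's
    featurization (6-dim node features, distance-annotated radius edges).

    Parameters mirror :class:`ModelConfig`; fitted state lives in
    ``model_`` (the :class:`TrainedModel`), ``classes_`` and the loss
    trajectories ``train_losses_`` / ``val_losses_``.
    """

    def __init__(
        self,
        hidden_units: int = 128,
        dropout: float = 0.2,
        learning_rate: float = 1e-5,
        l2_weight: float = 1e-3,
        patience: int = 50,
        max_epochs: int = 100,
        pooling_ratio: float = 0.8,
        batch_size: int = 16,
        seed: int = 0,
        val_fraction: float = 0.1,
    ):
        self.hidden_units = hidden_units
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.l2_weight = l2_weight
        self.patience = patience
        self.max_epochs = max_epochs
        self.pooling_ratio = pooling_ratio
        self.batch_size = batch_size
        self.seed = seed
        self.val_fraction = val_fraction

    # -- sklearn plumbing ---------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "hidden_units dropout learning_rate l2_weight patience "
                "max_epochs pooling_ratio batch_size seed val_fraction".split()
            )
        }

    def set_params(self, **kwargs) -> "GraphStabilityClassifier":
        valid = self.get_params()
        for k, v in kwargs.items():
            if k not in valid:
                raise ValueError(f"invalid parameter {k!r} for GraphStabilityClassifier")
            setattr(self, k, v)
        return self

    def _config(self) -> ModelConfig:
        return ModelConfig(**self.get_params())

    # -- estimator API ------------------------------------------------------
    def fit(self, X: Sequence[ProteinGraph], y=None) -> "GraphStabilityClassifier":
        graphs = list(X)
        if y is None:
            y = [g.label for g in graphs]
            if any(lab is None for lab in y):
                raise ValueError("unlabeled graph passed to fit without explicit y")
        y = np.asarray(y, dtype=int)
        config = self._config()
        untrained = init_model(config)
        self.model_ = train(untrained, graphs, y)
        self.classes_ = np.array([0, 1])
        self.train_losses_ = self.model_.train_losses
        self.val_losses_ = self.model_.val_losses
        self.n_epochs_ = self.model_.stopped_epoch
        return self

    def predict_proba(self, X: Sequence[ProteinGraph]) -> np.ndarray:
        self._check_fitted()
        p = predict_proba(self.model_, list(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X: Sequence[ProteinGraph]) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def score(self, X: Sequence[ProteinGraph], y) -> float:
        from sklearn.metrics import accuracy_score

        return float(accuracy_score(np.asarray(y, dtype=int), self.predict(X)))

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("GraphStabilityClassifier is not fitted yet; call fit first")
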