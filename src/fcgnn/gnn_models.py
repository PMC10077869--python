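"""Graph neural network base classifiers and the stacking ensemble.

Three base models classify a subject's connectome graph into two groups:

* **GCN** — spectral graph convolution: each layer propagates node
  features through the symmetrically degree-normalised adjacency with
  self-loops, ``act(D^-1/2 (A+I) D^-1/2 X W)``; ReLU, dropout 0.3.
* **GAT** — multi-head graph attention (8 heads): neighbour messages are
  weighted by softmax-normalised attention coefficients scored with a
  leaky-ReLU; heads are concatenated on hidden layers and averaged on
  the last; eLU, dropout 0.5.
* **GraphSAGE** — three layers (K = 3, hidden 64): each node combines a
  transform of itself with a transform of the mean of its neighbours;
  ReLU, dropout 0.3.

Every base ends with global mean pooling over the graph's nodes and a
fully connected classification layer.  All bases train with Adam
(learning rate 0.01, weight decay 5e-4) on cross-entropy.  The stacking
ensemble concatenates the bases' output features (pre-softmax logits by
default) and feeds them to a small fully connected meta head trained
with the same loss; bases are frozen during meta training by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from ._tensor import (
    Adam,
    EdgeAggSpec,
    ScatterSpec,
    SegmentSpec,
    Tensor,
    edge_weighted_matmul,
)
from .connectome import ConnectomeGraph

__all__ = [
    "BaseModelConfig",
    "OptimizerConfig",
    "EnsembleConfig",
    "GraphBatch",
    "prepare_graphs",
    "make_batch",
    "gcn_layer",
    "gat_layer",
    "sage_layer",
    "BaseGNN",
    "base_forward",
    "train_base",
    "EnsembleModel",
    "ensemble_fit",
    "ensemble_predict",
    "save_model",
    "load_model",
]

TRAIN_DTYPE = np.float32  # training numerics; contract ops run in float64
N_CLASSES = 2
LEAKY_SLOPE = 0.2
CHECKPOINT_VERSION = 1

_ARCH_DEFAULTS = {
    "gcn": dict(n_layers=3, hidden_dim=64, heads=1, dropout=0.3, activation="relu"),
    "gat": dict(n_layers=3, hidden_dim=64, heads=8, dropout=0.5, activation="elu"),
    "sage": dict(n_layers=3, hidden_dim=64, heads=1, dropout=0.3, activation="relu"),
}


@dataclass
class BaseModelConfig:
    """Architecture hyperparameters of one base classifier.

    Defaults per architecture follow the study settings: GAT has 3
    attention layers with 8 heads, eLU and dropout 0.5; GCN uses ReLU
    and dropout 0.3; GraphSAGE has K = 3 layers of 64 hidden units,
    ReLU and dropout 0.3.  All share global mean pooling.
    """

    arch: str = "gcn"
    n_layers: int = 3
    hidden_dim: int = 64
    heads: int = 1
    dropout: float = 0.3
    activation: str = "relu"
    readout: str = "global_mean"

    def __post_init__(self):
        if self.arch not in _ARCH_DEFAULTS:
            raise ValueError(f"unknown arch {self.arch!r}")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.activation not in ("relu", "elu"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.readout != "global_mean":
            raise ValueError("only global_mean readout is supported")
        if self.n_layers < 1 or self.hidden_dim < 1 or self.heads < 1:
            raise ValueError("n_layers, hidden_dim, heads must be positive")
        if self.arch == "gat" and self.hidden_dim % self.heads != 0:
            raise ValueError("gat hidden_dim must be divisible by heads")

    @classmethod
    def for_arch(cls, arch: str, **overrides) -> "BaseModelConfig":
        kw = dict(_ARCH_DEFAULTS[arch])
        kw.update(overrides)
        return cls(arch=arch, **kw)


@dataclass
class OptimizerConfig:
    learning_rate: float = 0.01
    weight_decay: float = 5e-4
    epochs: int = 150
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


@dataclass
class EnsembleConfig:
    """Stacking configuration: which base outputs feed the meta head.

    ``combine`` selects pre-softmax logits (default) or softmax
    probabilities as the bases' "output features"; ``meta_hidden=0``
    means a single linear layer before the final softmax;
    ``freeze_bases`` keeps the independently trained bases fixed while
    the meta head learns.
    """

    base_configs: tuple = field(default_factory=lambda: (
        BaseModelConfig.for_arch("gcn"),
        BaseModelConfig.for_arch("gat"),
        BaseModelConfig.for_arch("sage"),
    ))
    combine: str = "concat_logits"
    meta_hidden: int = 0
    freeze_bases: bool = True

    def __post_init__(self):
        if len(self.base_configs) != 3:
            raise ValueError("ensemble requires exactly three base models")
        if self.combine not in ("concat_logits", "concat_probs"):
            raise ValueError(f"unknown combine {self.combine!r}")
        if self.meta_hidden < 0:
            raise ValueError("meta_hidden must be >= 0")


# ---------------------------------------------------------------------------
# Batched message-passing structure
# ---------------------------------------------------------------------------

class PreppedGraph:
    """Edge arrays of one graph, laid out for batched segment reductions.

    Directed edge lists are sorted by destination so that concatenating
    graphs (with node-index offsets) keeps the global list sorted, which
    lets segment sums run on contiguous slices.
    """

    __slots__ = ("n_nodes", "x", "src_sl", "dst_sl", "gcn_coef",
                 "src_nb", "dst_nb", "inv_deg", "label", "subject_id")

    def __init__(self, g: ConnectomeGraph):
        a = np.asarray(g.adjacency, dtype=np.float64)
        n = g.n_nodes
        self.n_nodes = n
        self.x = np.asarray(g.node_features, dtype=np.float64)
        self.label = g.label
        self.subject_id = g.subject_id

        pattern = a != 0
        w = np.abs(a)  # degrees/propagation need nonnegative weights
        # self-loop-augmented structure (GCN propagation, GAT attention)
        pat_sl = pattern | np.eye(n, dtype=bool)
        dst_sl, src_sl = np.nonzero(pat_sl)  # row-major: sorted by dst
        self.src_sl = src_sl.astype(np.int64)
        self.dst_sl = dst_sl.astype(np.int64)
        w_sl = np.where(np.eye(n, dtype=bool), 1.0, w)[dst_sl, src_sl]
        deg = w.sum(axis=1) + 1.0
        self.gcn_coef = w_sl / np.sqrt(deg[dst_sl] * deg[src_sl])
        # neighbour-only structure (SAGE mean aggregation)
        dst_nb, src_nb = np.nonzero(pattern)
        self.src_nb = src_nb.astype(np.int64)
        self.dst_nb = dst_nb.astype(np.int64)
        counts = pattern.sum(axis=1).astype(np.float64)
        self.inv_deg = np.where(counts > 0, 1.0 / np.maximum(counts, 1.0), 0.0)


class GraphBatch:
    """A block-diagonal stack of graphs with per-node graph membership."""

    def __init__(self, graphs: Sequence[PreppedGraph], dtype=TRAIN_DTYPE,
                 require_labels: bool = True):
        if len(graphs) == 0:
            raise ValueError("empty batch")
        sizes = np.array([g.n_nodes for g in graphs])
        offsets = np.concatenate(([0], np.cumsum(sizes)[:-1]))
        n_total = int(sizes.sum())
        self.n_graphs = len(graphs)
        self.n_nodes = n_total
        self.x = np.concatenate([g.x for g in graphs]).astype(dtype)
        self.src_sl = np.concatenate(
            [g.src_sl + o for g, o in zip(graphs, offsets)])
        dst_sl = np.concatenate([g.dst_sl + o for g, o in zip(graphs, offsets)])
        self.spec_sl = SegmentSpec(dst_sl, n_total)
        self.gcn_coef = np.concatenate(
            [g.gcn_coef for g in graphs]).astype(dtype)
        self.src_nb = np.concatenate(
            [g.src_nb + o for g, o in zip(graphs, offsets)])
        dst_nb = np.concatenate([g.dst_nb + o for g, o in zip(graphs, offsets)])
        inv_deg = np.concatenate([g.inv_deg for g in graphs]).astype(dtype)
        self.scatter_sl = ScatterSpec(self.src_sl, n_total)
        self.scatter_dst = ScatterSpec(dst_sl, n_total)
        # constant propagation operators as CSR matrices
        indptr_sl = np.searchsorted(dst_sl, np.arange(n_total + 1))
        self.gcn_mat = sp.csr_matrix(
            (self.gcn_coef.ravel(), self.src_sl, indptr_sl),
            shape=(n_total, n_total))  # symmetric: it is its own transpose
        indptr_nb = np.searchsorted(dst_nb, np.arange(n_total + 1))
        self.sage_mat = sp.csr_matrix(
            (inv_deg[dst_nb], self.src_nb, indptr_nb),
            shape=(n_total, n_total))
        self.sage_mat_t = self.sage_mat.T.tocsr()
        pool_indptr = np.concatenate(([0], np.cumsum(sizes)))
        inv_size = (1.0 / sizes).astype(dtype)
        self.pool_mat = sp.csr_matrix(
            (np.repeat(inv_size, sizes), np.arange(n_total), pool_indptr),
            shape=(self.n_graphs, n_total))
        self.pool_mat_t = self.pool_mat.T.tocsr()
        self.att = EdgeAggSpec(self.src_sl, dst_sl, n_total)
        labels = [g.label for g in graphs]
        if any(l is None for l in labels):
            if require_labels:
                raise ValueError("batch contains unlabeled graphs")
            self.labels = None
        else:
            self.labels = np.asarray(labels, dtype=np.int64)
            if not np.all(np.isin(self.labels, (0, 1))):
                raise ValueError("labels must be in {0, 1}")


def prepare_graphs(graphs: Sequence[ConnectomeGraph]) -> list[PreppedGraph]:
    return [PreppedGraph(g) for g in graphs]


def make_batch(graphs: Sequence[PreppedGraph], dtype=TRAIN_DTYPE,
               require_labels: bool = True) -> GraphBatch:
    return GraphBatch(graphs, dtype=dtype, require_labels=require_labels)


# ---------------------------------------------------------------------------
# Shared differentiable layer kernels
# ---------------------------------------------------------------------------

def _activate(t: Tensor, activation: str | None) -> Tensor:
    if activation is None:
        return t
    if activation == "relu":
        return t.relu()
    if activation == "elu":
        return t.elu()
    raise ValueError(f"unknown activation {activation!r}")


def _gcn_propagate(h: Tensor, mat) -> Tensor:
    """Propagate through the degree-normalised self-loop adjacency
    (symmetric, so it is its own transpose in the backward pass)."""
    return h.spmm(mat, mat)


def _gat_attention(h3: Tensor, a_src: Tensor, a_dst: Tensor,
                   src, dst, spec, agg, src_scatter=None,
                   dst_scatter=None) -> "tuple[Tensor, np.ndarray]":
    """Multi-head attention aggregation; returns (N,H,F') output and the
    (E,H) attention coefficients (self-loops always included, so every
    row of the per-destination softmax is well defined)."""
    s_src = (h3 * a_src).sum(axis=2)            # (N, H)
    s_dst = (h3 * a_dst).sum(axis=2)
    e = (s_src.gather_rows(src, src_scatter)
         + s_dst.gather_rows(dst, dst_scatter)).leaky_relu(LEAKY_SLOPE)
    shift = spec.segment_max(e.data)[dst]        # constant; softmax is shift-invariant
    ex = e.add_const(-shift).exp()
    denom = ex.segment_sum(spec)                 # (N, H)
    alpha = ex / denom.gather_rows(dst, dst_scatter)   # (E, H)
    return edge_weighted_matmul(alpha, h3, agg), alpha.data


def _sage_aggregate(x: Tensor, mat, mat_t) -> Tensor:
    """Mean of neighbour features; zero vector for empty neighbourhoods."""
    return x.spmm(mat, mat_t)


def _single_graph_structure(n_nodes: int, edges, weights=None):
    """Edge arrays for the functional layer entry points."""
    a = np.zeros((n_nodes, n_nodes))
    for idx, (i, j) in enumerate(edges):
        w = 1.0 if weights is None else weights[idx]
        a[i, j] = a[j, i] = w
    g = ConnectomeGraph(subject_id="", n_nodes=n_nodes,
                        edges={(min(i, j), max(i, j)) for i, j in edges},
                        adjacency=a, node_features=np.zeros((n_nodes, 1)))
    return PreppedGraph(g)


# ---------------------------------------------------------------------------
# Functional layer contracts (float64, single graph)
# ---------------------------------------------------------------------------

def gcn_layer(features: np.ndarray, adjacency: np.ndarray,
              weight: np.ndarray | None = None,
              activation: str | None = None) -> np.ndarray:
    """One graph-convolution layer act(D^-1/2 (A+I) D^-1/2 X W).

    `adjacency` must be symmetric and nonnegative with a zero diagonal;
    self-loops are added internally.  With `weight=None`, W = I.
    """
    x = np.asarray(features, dtype=np.float64)
    a = np.asarray(adjacency, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] != a.shape[1] or a.shape[0] != x.shape[0]:
        raise ValueError("adjacency/features dimension mismatch")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(a < 0) or np.any(np.diag(a) != 0):
        raise ValueError("adjacency must be nonnegative with zero diagonal")
    if weight is not None:
        weight = np.asarray(weight, dtype=np.float64)
        if weight.shape[0] != x.shape[1]:
            raise ValueError("weight/features dimension mismatch")
    n = a.shape[0]
    a_sl = a + np.eye(n)
    dst, src = np.nonzero(a_sl)
    deg = a.sum(axis=1) + 1.0
    coef = a_sl[dst, src] / np.sqrt(deg[dst] * deg[src])
    indptr = np.searchsorted(dst, np.arange(n + 1))
    mat = sp.csr_matrix((coef, src, indptr), shape=(n, n))
    h = Tensor(x) if weight is None else Tensor(x) @ Tensor(weight)
    out = _gcn_propagate(h, mat)
    return _activate(out, activation).data


def gat_layer(features: np.ndarray, edges, heads: int = 8,
              out_dim: int = 8, weight: np.ndarray | None = None,
              attn_src: np.ndarray | None = None,
              attn_dst: np.ndarray | None = None,
              concat: bool = True, activation: str | None = None,
              seed: int = 0, return_attention: bool = False):
    """One multi-head graph-attention layer over undirected `edges`.

    Self-attention is always enabled, so isolated nodes attend to
    themselves with coefficient 1.  Heads are concatenated when
    `concat`, averaged otherwise.  Unsupplied parameters are drawn from
    a Glorot-uniform initialisation seeded by `seed`.
    """
    x = np.asarray(features, dtype=np.float64)
    n, f = x.shape
    rng = np.random.default_rng(seed)
    if weight is None:
        weight = _glorot(rng, (f, heads * out_dim), np.float64)
    if attn_src is None:
        attn_src = _glorot(rng, (1, heads, out_dim), np.float64)
    if attn_dst is None:
        attn_dst = _glorot(rng, (1, heads, out_dim), np.float64)
    directed = {(i, i) for i in range(n)}
    for i, j in edges:
        directed.add((int(i), int(j)))
        directed.add((int(j), int(i)))
    pairs = np.array(sorted(directed, key=lambda p: (p[1], p[0])), dtype=np.int64)
    src, dst = pairs[:, 0], pairs[:, 1]
    spec = SegmentSpec(dst, n)
    agg = EdgeAggSpec(src, dst, n)
    h3 = (Tensor(x) @ Tensor(np.asarray(weight, dtype=np.float64))
          ).reshape(n, heads, out_dim)
    out3, alpha = _gat_attention(h3, Tensor(np.asarray(attn_src, dtype=np.float64)),
                                 Tensor(np.asarray(attn_dst, dtype=np.float64)),
                                 src, dst, spec, agg)
    out = out3.reshape(n, heads * out_dim) if concat else out3.mean(axis=1)
    out = _activate(out, activation).data
    if return_attention:
        return out, (pairs, alpha)
    return out


def sage_layer(features: np.ndarray, edges,
               w_self: np.ndarray | None = None,
               w_neigh: np.ndarray | None = None,
               activation: str | None = None) -> np.ndarray:
    """One GraphSAGE layer act(W_self x_i + W_neigh mean_{j in N(i)} x_j).

    The mean over an empty neighbourhood is the zero vector, so isolated
    nodes depend only on their own transform.  Defaults are identity
    transforms.
    """
    x = np.asarray(features, dtype=np.float64)
    n, f = x.shape
    w_self = np.eye(f) if w_self is None else np.asarray(w_self, dtype=np.float64)
    w_neigh = np.eye(f) if w_neigh is None else np.asarray(w_neigh, dtype=np.float64)
    g = _single_graph_structure(n, [(int(i), int(j)) for i, j in edges])
    indptr = np.searchsorted(g.dst_nb, np.arange(n + 1))
    mat = sp.csr_matrix((g.inv_deg[g.dst_nb], g.src_nb, indptr), shape=(n, n))
    xt = Tensor(x)
    agg = _sage_aggregate(xt, mat, mat.T.tocsr())
    out = xt @ Tensor(w_self) + agg @ Tensor(w_neigh)
    return _activate(out, activation).data


# ---------------------------------------------------------------------------
# Base models
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, shape, dtype) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    if len(shape) == 3:  # attention vectors (1, H, F')
        fan_in, fan_out = shape[-1], 1
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=shape).astype(dtype)


class BaseGNN:
    """One base graph classifier (GCN, GAT or GraphSAGE).

    Layers per the architecture config, global mean pooling, and a fully
    connected layer producing one logit row per graph.
    """

    def __init__(self, cfg: BaseModelConfig, in_dim: int,
                 n_classes: int = N_CLASSES, seed: int = 0,
                 rng: np.random.Generator | None = None):
        self.cfg = cfg
        self.in_dim = in_dim
        self.n_classes = n_classes
        rng = rng if rng is not None else np.random.default_rng(seed)
        self.params: list[Tensor] = []
        self._layers: list[dict] = []
        d = in_dim
        dt = TRAIN_DTYPE
        for li in range(cfg.n_layers):
            layer: dict = {}
            if cfg.arch == "gat":
                last = li == cfg.n_layers - 1
                fh = cfg.hidden_dim // cfg.heads
                layer["W"] = self._param(_glorot(rng, (d, cfg.heads * fh), dt))
                layer["a_src"] = self._param(_glorot(rng, (1, cfg.heads, fh), dt))
                layer["a_dst"] = self._param(_glorot(rng, (1, cfg.heads, fh), dt))
                layer["fh"] = fh
                layer["concat"] = not last
                d = cfg.heads * fh if not last else fh
                layer["b"] = self._param(np.zeros((d,), dtype=dt))
            elif cfg.arch == "gcn":
                layer["W"] = self._param(_glorot(rng, (d, cfg.hidden_dim), dt))
                layer["b"] = self._param(np.zeros((cfg.hidden_dim,), dtype=dt))
                d = cfg.hidden_dim
            else:  # sage
                layer["W_self"] = self._param(_glorot(rng, (d, cfg.hidden_dim), dt))
                layer["W_neigh"] = self._param(_glorot(rng, (d, cfg.hidden_dim), dt))
                layer["b"] = self._param(np.zeros((cfg.hidden_dim,), dtype=dt))
                d = cfg.hidden_dim
            self._layers.append(layer)
        self.out_W = self._param(_glorot(rng, (d, n_classes), dt))
        self.out_b = self._param(np.zeros((n_classes,), dtype=dt))
        self.history: list[float] = []

    def _param(self, data: np.ndarray) -> Tensor:
        t = Tensor(data, requires_grad=True)
        self.params.append(t)
        return t

    def forward(self, batch: GraphBatch, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Logits per graph; dropout applied only when `training`."""
        cfg = self.cfg
        h = Tensor(batch.x)
        for layer in self._layers:
            if cfg.arch == "gcn":
                h = _gcn_propagate(h @ layer["W"], batch.gcn_mat)
                h = h + layer["b"]
            elif cfg.arch == "gat":
                n = batch.n_nodes
                h3 = (h @ layer["W"]).reshape(n, cfg.heads, layer["fh"])
                out3, _ = _gat_attention(h3, layer["a_src"], layer["a_dst"],
                                         batch.src_sl, batch.spec_sl.ids,
                                         batch.spec_sl, batch.att,
                                         src_scatter=batch.scatter_sl,
                                         dst_scatter=batch.scatter_dst)
                h = (out3.reshape(n, cfg.heads * layer["fh"])
                     if layer["concat"] else out3.mean(axis=1))
                h = h + layer["b"]
            else:
                agg = _sage_aggregate(h, batch.sage_mat, batch.sage_mat_t)
                h = h @ layer["W_self"] + agg @ layer["W_neigh"] + layer["b"]
            h = _activate(h, cfg.activation)
            if training and cfg.dropout > 0:
                if rng is None:
                    raise ValueError("training forward pass needs an rng")
                keep = (rng.random(h.data.shape) >= cfg.dropout)
                h = h.scale(keep.astype(h.data.dtype) / (1.0 - cfg.dropout))
        pooled = h.spmm(batch.pool_mat, batch.pool_mat_t)
        return pooled @ self.out_W + self.out_b

    def predict_logits(self, graphs: Sequence[PreppedGraph]) -> np.ndarray:
        batch = make_batch(graphs, require_labels=False)
        return self.forward(batch, training=False).data.astype(np.float64)

    def predict_proba(self, graphs: Sequence[PreppedGraph]) -> np.ndarray:
        return _softmax_np(self.predict_logits(graphs))


def _softmax_np(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def base_forward(batch: GraphBatch, model: BaseGNN,
                 training: bool = False,
                 rng: np.random.Generator | None = None):
    """Run one base model on a batch; returns (logits, probabilities)."""
    logits = model.forward(batch, training=training, rng=rng).data
    return logits, _softmax_np(logits.astype(np.float64))


def _as_prepped(graphs) -> list[PreppedGraph]:
    return [g if isinstance(g, PreppedGraph) else PreppedGraph(g)
            for g in graphs]


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")


def train_base(train_graphs, cfg: BaseModelConfig,
               opt: OptimizerConfig) -> BaseGNN:
    """Train one base classifier with Adam on cross-entropy.

    Fully reproducible given `opt.seed`, which drives initialisation,
    epoch shuffling, and dropout masks.
    """
    prepped = _as_prepped(train_graphs)
    if len(prepped) < 2:
        raise ValueError("need at least 2 training graphs")
    labels = np.array([g.label for g in prepped])
    _check_two_classes(labels)
    in_dim = prepped[0].x.shape[1]
    rng = np.random.default_rng(opt.seed)
    model = BaseGNN(cfg, in_dim, rng=rng)
    optimizer = Adam(model.params, lr=opt.learning_rate,
                     weight_decay=opt.weight_decay)
    n = len(prepped)
    for _ in range(opt.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, opt.batch_size):
            idx = perm[start:start + opt.batch_size]
            batch = make_batch([prepped[i] for i in idx])
            logits = model.forward(batch, training=True, rng=rng)
            loss = logits.cross_entropy(batch.labels)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        model.history.append(epoch_loss / n_batches)
    return model


# ---------------------------------------------------------------------------
# Stacking ensemble
# ---------------------------------------------------------------------------

class EnsembleModel:
    """Three trained bases plus a fully connected meta head."""

    def __init__(self, bases: Sequence[BaseGNN], cfg: EnsembleConfig,
                 seed: int = 0, rng: np.random.Generator | None = None):
        if len(bases) != 3:
            raise ValueError("ensemble requires exactly three base models")
        cs = {b.n_classes for b in bases}
        if len(cs) != 1:
            raise ValueError("base output dimensions differ")
        self.n_classes = cs.pop()
        self.bases = list(bases)
        self.cfg = cfg
        rng = rng if rng is not None else np.random.default_rng(seed)
        dt = TRAIN_DTYPE
        d_in = 3 * self.n_classes
        self.meta_params: list[Tensor] = []
        if cfg.meta_hidden > 0:
            self.meta_W1 = self._param(_glorot(rng, (d_in, cfg.meta_hidden), dt))
            self.meta_b1 = self._param(np.zeros((cfg.meta_hidden,), dtype=dt))
            self.meta_W2 = self._param(
                _glorot(rng, (cfg.meta_hidden, self.n_classes), dt))
            self.meta_b2 = self._param(np.zeros((self.n_classes,), dtype=dt))
        else:
            self.meta_W1 = self._param(_glorot(rng, (d_in, self.n_classes), dt))
            self.meta_b1 = self._param(np.zeros((self.n_classes,), dtype=dt))
            self.meta_W2 = None
            self.meta_b2 = None
        self.history: list[float] = []

    def _param(self, data: np.ndarray) -> Tensor:
        t = Tensor(data, requires_grad=True)
        self.meta_params.append(t)
        return t

    # -- meta head --------------------------------------------------------
    def meta_forward(self, feats: Tensor) -> Tensor:
        h = feats @ self.meta_W1 + self.meta_b1
        if self.meta_W2 is not None:
            h = h.relu() @ self.meta_W2 + self.meta_b2
        return h

    def base_features(self, graphs: Sequence[PreppedGraph]) -> np.ndarray:
        """Concatenated output features of the (frozen) bases, (n, 3C)."""
        feats = []
        for b in self.bases:
            z = b.predict_logits(graphs)
            feats.append(_softmax_np(z) if self.cfg.combine == "concat_probs"
                         else z)
        return np.concatenate(feats, axis=1)

    def predict_proba(self, graphs) -> np.ndarray:
        prepped = _as_prepped(graphs)
        feats = Tensor(self.base_features(prepped).astype(TRAIN_DTYPE))
        logits = self.meta_forward(feats).data.astype(np.float64)
        return _softmax_np(logits)


def ensemble_fit(bases: Sequence[BaseGNN], train_graphs,
                 cfg: EnsembleConfig, opt: OptimizerConfig) -> EnsembleModel:
    """Fit the stacking meta head on the bases' output features.

    With `cfg.freeze_bases` (the default) the base weights are left
    untouched and their features are computed once; otherwise the bases
    are fine-tuned jointly with the meta head.
    """
    prepped = _as_prepped(train_graphs)
    labels = np.array([g.label for g in prepped])
    _check_two_classes(labels)
    rng = np.random.default_rng(opt.seed)
    ens = EnsembleModel(bases, cfg, rng=rng)
    n = len(prepped)
    if cfg.freeze_bases:
        feats_all = ens.base_features(prepped).astype(TRAIN_DTYPE)
        params = ens.meta_params
    else:
        params = ens.meta_params + [p for b in bases for p in b.params]
    optimizer = Adam(params, lr=opt.learning_rate,
                     weight_decay=opt.weight_decay)
    for _ in range(opt.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, opt.batch_size):
            idx = perm[start:start + opt.batch_size]
            y = labels[idx]
            if cfg.freeze_bases:
                feats = Tensor(feats_all[idx])
            else:
                batch = make_batch([prepped[i] for i in idx])
                outs = []
                for b in ens.bases:
                    z = b.forward(batch, training=True, rng=rng)
                    outs.append(_softmax_t(z)
                                if cfg.combine == "concat_probs" else z)
                feats = Tensor.concat(outs, axis=1)
            logits = ens.meta_forward(feats)
            loss = logits.cross_entropy(y)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        ens.history.append(epoch_loss / n_batches)
    return ens


def _softmax_t(t: Tensor) -> Tensor:
    shift = t.data.max(axis=1, keepdims=True)
    e = t.add_const(-shift).exp()
    return e / e.sum(axis=1, keepdims=True)


def ensemble_predict(ensemble: EnsembleModel, graphs):
    """Class probabilities and hard labels (ties resolve to class 0)."""
    probs = ensemble.predict_proba(graphs)
    labels = np.argmax(probs, axis=1)  # argmax takes the first maximum
    return probs, labels


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_model(model, path) -> None:
    """Serialise a base or ensemble model to a self-describing JSON file."""
    if isinstance(model, BaseGNN):
        payload = {
            "format": "fcgnn-checkpoint", "version": CHECKPOINT_VERSION,
            "kind": "base", "config": asdict(model.cfg),
            "in_dim": model.in_dim, "n_classes": model.n_classes,
            "weights": [p.data.astype(np.float64).tolist()
                        for p in model.params],
        }
    elif isinstance(model, EnsembleModel):
        cfgd = asdict(model.cfg)
        cfgd["base_configs"] = [asdict(c) for c in model.cfg.base_configs]
        payload = {
            "format": "fcgnn-checkpoint", "version": CHECKPOINT_VERSION,
            "kind": "ensemble", "config": cfgd,
            "bases": [{"config": asdict(b.cfg), "in_dim": b.in_dim,
                       "n_classes": b.n_classes,
                       "weights": [p.data.astype(np.float64).tolist()
                                   for p in b.params]}
                      for b in model.bases],
            "meta_weights": [p.data.astype(np.float64).tolist()
                             for p in model.meta_params],
        }
    else:
        raise TypeError(f"cannot checkpoint {type(model).__name__}")
    with open(path, "w") as fh:
        json.dump(payload, fh)


def _load_base(entry: dict) -> BaseGNN:
    cfg = BaseModelConfig(**entry["config"])
    model = BaseGNN(cfg, entry["in_dim"], n_classes=entry["n_classes"])
    for p, w in zip(model.params, entry["weights"]):
        p.data = np.asarray(w, dtype=TRAIN_DTYPE)
    return model


def load_model(path):
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "fcgnn-checkpoint":
        raise ValueError("not an fcgnn checkpoint")
    if payload["kind"] == "base":
        return _load_base(payload)
    cfgd = dict(payload["config"])
    cfgd["base_configs"] = tuple(
        BaseModelConfig(**c) for c in cfgd["base_configs"])
    cfg = EnsembleConfig(**cfgd)
    bases = [_load_base(e) for e in payload["bases"]]
    ens = EnsembleModel(bases, cfg)
    for p, w in zip(ens.meta_params, payload["meta_weights"]):
        p.data = np.asarray(w, dtype=TRAIN_DTYPE)
    return ens
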