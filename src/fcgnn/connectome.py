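"""Functional-connectivity matrices and their KNN graph representation.

A subject's resting-state scan is summarised as an R x R matrix of
Fisher-z-transformed Pearson correlations between the mean BOLD time
series of R atlas regions (R = 160 for the Dosenbach atlas; AAL and
Craddock parcellations simply change R).  The dense matrix is then
sparsified into a weighted undirected graph: each region keeps edges to
its k strongest neighbours (by |z|), the directed selections are
symmetrised by union, and each node carries its full connectivity row as
its feature vector.  These graphs are the input to the GNN classifiers
in :mod:`fcgnn.gnn_models`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ROITimeSeries",
    "FCMatrix",
    "GraphConfig",
    "ConnectomeGraph",
    "fisher_z",
    "compute_fc",
    "build_knn_graph",
    "graph_to_edge_list",
    "graph_from_edge_list",
]

DEFAULT_R_CLIP = 0.999999


@dataclass
class ROITimeSeries:
    """Per-subject region-averaged BOLD signal, T timepoints x R regions."""

    subject_id: str
    values: np.ndarray
    region_labels: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D (T x R) array")
        t, r = self.values.shape
        if t < 3:
            raise ValueError(f"need at least 3 timepoints, got {t}")
        if r < 2:
            raise ValueError(f"need at least 2 regions, got {r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains missing/non-finite values")
        sd = self.values.std(axis=0)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            raise ValueError(
                f"region(s) {dead.tolist()} have zero variance; "
                "correlation is undefined")

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class FCMatrix:
    """Symmetric Fisher-z connectivity matrix with zero diagonal."""

    subject_id: str
    z: np.ndarray
    r_clip: float = DEFAULT_R_CLIP

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=np.float64)
        if self.z.ndim != 2 or self.z.shape[0] != self.z.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("FC matrix contains non-finite entries")
        if not np.array_equal(self.z, self.z.T):
            raise ValueError("FC matrix must be exactly symmetric")
        if np.any(np.diag(self.z) != 0):
            raise ValueError("FC matrix diagonal must be zero")

    @property
    def n_regions(self) -> int:
        return self.z.shape[0]


@dataclass
class GraphConfig:
    """KNN sparsification settings.

    k
        neighbours each node selects (the paper leaves k unstated;
        10 is the package default — see the methods note for sensitivity).
    rank_by
        ``abs_weight`` ranks neighbours by |z| (strength regardless of
        sign, the default) or ``signed_weight`` by raw z.
    weight_mode
        ``abs_z`` (default, nonnegative adjacency suitable for normalised
        propagation), ``signed_z``, or ``binary``.
    """

    k: int = 10
    rank_by: str = "abs_weight"
    weight_mode: str = "abs_z"

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.rank_by not in ("abs_weight", "signed_weight"):
            raise ValueError(f"unknown rank_by {self.rank_by!r}")
        if self.weight_mode not in ("abs_z", "signed_z", "binary"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")


@dataclass
class ConnectomeGraph:
    """Weighted undirected KNN graph of one subject's connectome.

    ``adjacency`` is the symmetric weighted matrix A with zero diagonal;
    ``node_features`` row i is node i's full Fisher-z profile; ``edges``
    holds unordered index pairs (i < j).
    """

    subject_id: str
    n_nodes: int
    edges: set = field(default_factory=set)
    adjacency: np.ndarray | None = None
    node_features: np.ndarray | None = None
    label: int | None = None
    site: str | None = None


def fisher_z(r: float, r_clip: float = DEFAULT_R_CLIP):
    """Fisher z-transform arctanh(r), with |r| clipped to `r_clip`.

    Variance-stabilising map of a correlation onto the real line; the
    clip keeps perfectly correlated (degenerate or duplicated) series
    finite instead of diverging.
    """
    r = np.asarray(r, dtype=np.float64)
    if np.any(np.abs(r) > 1):
        raise ValueError("correlation outside [-1, 1]")
    if not 0 < r_clip < 1:
        raise ValueError("r_clip must lie in (0, 1)")
    out = np.arctanh(np.clip(r, -r_clip, r_clip))
    return out if out.ndim else float(out)


def compute_fc(ts: ROITimeSeries, r_clip: float = DEFAULT_R_CLIP) -> FCMatrix:
    """Pearson-correlate every region pair and Fisher-z the result.

    The diagonal is forced to zero (self-connectivity carries no
    information and arctanh(1) diverges).
    """
    if not 0 < r_clip < 1:
        raise ValueError("r_clip must lie in (0, 1)")
    r = np.corrcoef(ts.values, rowvar=False)
    np.fill_diagonal(r, 0.0)
    z = np.arctanh(np.clip(r, -r_clip, r_clip))
    z = (z + z.T) / 2.0  # enforce exact symmetry against rounding
    return FCMatrix(subject_id=ts.subject_id, z=z, r_clip=r_clip)


def build_knn_graph(fc: FCMatrix, cfg: GraphConfig) -> ConnectomeGraph:
    """Sparsify an FC matrix into a weighted undirected KNN graph.

    Each node selects its cfg.k strongest neighbours (rank key per
    cfg.rank_by, ties broken toward the lower node index); the edge set
    is the union of the directed selections, so degrees can exceed k
    after symmetrisation but never fall below it.
    """
    r = fc.n_regions
    if not 1 <= cfg.k <= r - 1:
        raise ValueError(f"k={cfg.k} out of range [1, {r - 1}]")
    z = fc.z
    if not np.array_equal(z, z.T):
        raise ValueError("adjacency source matrix must be symmetric")
    key = np.abs(z) if cfg.rank_by == "abs_weight" else z.copy()
    np.fill_diagonal(key, -np.inf)  # never select self
    # stable ranking: sort descending by key, ties toward lower index
    order = np.argsort(-key, axis=1, kind="stable")
    chosen = order[:, : cfg.k]

    adjacency = np.zeros((r, r), dtype=np.float64)
    edges: set[tuple[int, int]] = set()
    for i in range(r):
        for j in chosen[i]:
            j = int(j)
            edges.add((min(i, j), max(i, j)))
    if cfg.weight_mode == "binary":
        for i, j in edges:
            adjacency[i, j] = adjacency[j, i] = 1.0
    else:
        for i, j in edges:
            w = abs(z[i, j]) if cfg.weight_mode == "abs_z" else z[i, j]
            adjacency[i, j] = adjacency[j, i] = w
    features = z.copy()
    return ConnectomeGraph(subject_id=fc.subject_id, n_nodes=r, edges=edges,
                           adjacency=adjacency, node_features=features)


def graph_to_edge_list(g: ConnectomeGraph) -> list[tuple[int, int, float]]:
    """Deterministic (i, j, weight) listing, i < j, lexicographic."""
    return [(i, j, float(g.adjacency[i, j])) for i, j in sorted(g.edges)]


def graph_from_edge_list(edge_list: Iterable[Sequence], n_nodes: int,
                         node_features: np.ndarray | None = None,
                         subject_id: str = "") -> ConnectomeGraph:
    """Inverse of :func:`graph_to_edge_list`; reproduces A exactly."""
    adjacency = np.zeros((n_nodes, n_nodes), dtype=np.float64)
    edges: set[tuple[int, int]] = set()
    for i, j, w in edge_list:
        i, j = int(i), int(j)
        if i == j:
            raise ValueError("self-loops are not allowed")
        edges.add((min(i, j), max(i, j)))
        adjacency[i, j] = adjacency[j, i] = float(w)
    return ConnectomeGraph(subject_id=subject_id, n_nodes=n_nodes, edges=edges,
                           adjacency=adjacency, node_features=node_features)
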