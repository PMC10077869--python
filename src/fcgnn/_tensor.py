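"""Compact reverse-mode automatic differentiation on numpy arrays.

The model code in :mod:`fcgnn.gnn_models` needs only a narrow set of
differentiable primitives: dense matmul, broadcast arithmetic, a few
pointwise nonlinearities, row gather / segment-sum (the sparse
message-passing pair), axis reductions, reshape/concat, and a fused
softmax cross-entropy.  Each primitive stores a closure that maps the
output gradient to parent gradients; :meth:`Tensor.backward` runs the
closures in reverse topological order.

Gradients accumulate into ``Tensor.grad`` (a numpy array of the same
shape and dtype as ``Tensor.data``).  Only tensors created with
``requires_grad=True``, or downstream of one, participate.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = ["Tensor", "SegmentSpec", "ScatterSpec", "EdgeAggSpec",
           "edge_weighted_matmul", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # leading added axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _spmm(mat: sp.csr_matrix, values: np.ndarray,
          n_out: int) -> np.ndarray:
    """Row reduction as a sparse matmul; flattens trailing axes."""
    flat = values.reshape(values.shape[0], -1)
    out = mat @ flat
    return out.reshape((n_out,) + values.shape[1:])


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction of derived tensors ---------------------------------
    @staticmethod
    def _result(data: np.ndarray, parents: Sequence["Tensor"],
                backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            # reference, not copy: accumulation below is out-of-place and
            # no caller mutates gradient arrays in place
            self.grad = g
        else:
            self.grad = self.grad + g

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other: "Tensor") -> "Tensor":
        a, b = self, other

        def backward(g):
            a._accum(_unbroadcast(g, a.data.shape))
            b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._result(a.data + b.data, (a, b), backward)

    def __sub__(self, other: "Tensor") -> "Tensor":
        a, b = self, other

        def backward(g):
            a._accum(_unbroadcast(g, a.data.shape))
            b._accum(_unbroadcast(-g, b.data.shape))

        return Tensor._result(a.data - b.data, (a, b), backward)

    def __mul__(self, other: "Tensor") -> "Tensor":
        a, b = self, other

        def backward(g):
            a._accum(_unbroadcast(g * b.data, a.data.shape))
            b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._result(a.data * b.data, (a, b), backward)

    def __truediv__(self, other: "Tensor") -> "Tensor":
        a, b = self, other

        def backward(g):
            a._accum(_unbroadcast(g / b.data, a.data.shape))
            b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return Tensor._result(a.data / b.data, (a, b), backward)

    def scale(self, c: float) -> "Tensor":
        """Multiply by a non-differentiable scalar or constant array."""
        a = self
        c = np.asarray(c, dtype=a.data.dtype) if not np.isscalar(c) else c

        def backward(g):
            a._accum(_unbroadcast(g * c, a.data.shape))

        return Tensor._result(a.data * c, (a,), backward)

    def add_const(self, c) -> "Tensor":
        a = self

        def backward(g):
            a._accum(g)

        return Tensor._result(a.data + c, (a,), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        a, b = self, other

        def backward(g):
            a._accum(g @ b.data.T)
            b._accum(a.data.T @ g)

        return Tensor._result(a.data @ b.data, (a, b), backward)

    __matmul__ = matmul

    # -- nonlinearities ---------------------------------------------------
    def relu(self) -> "Tensor":
        a = self
        out = np.maximum(a.data, 0)

        def backward(g):
            a._accum(g * (a.data > 0))

        return Tensor._result(out, (a,), backward)

    def elu(self, alpha: float = 1.0) -> "Tensor":
        a = self
        neg = a.data < 0
        out = np.where(neg, alpha * np.expm1(a.data), a.data)

        def backward(g):
            a._accum(g * np.where(neg, out + alpha, 1.0))

        return Tensor._result(out, (a,), backward)

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        a = self
        out = np.where(a.data > 0, a.data, slope * a.data)

        def backward(g):
            a._accum(g * np.where(a.data > 0, 1.0, slope))

        return Tensor._result(out, (a,), backward)

    def exp(self) -> "Tensor":
        a = self
        out = np.exp(a.data)

        def backward(g):
            a._accum(g * out)

        return Tensor._result(out, (a,), backward)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        a = self

        def backward(g):
            a._accum(g.reshape(a.data.shape))

        return Tensor._result(a.data.reshape(*shape), (a,), backward)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self

        def backward(g):
            if axis is None:
                a._accum(np.full_like(a.data, g))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._result(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims).scale(1.0 / n)

    @staticmethod
    def concat(tensors: Sequence["Tensor"], axis: int = 1) -> "Tensor":
        parts = tuple(tensors)
        sizes = [t.data.shape[axis] for t in parts]
        splits = np.cumsum(sizes)[:-1]

        def backward(g):
            for t, gg in zip(parts, np.split(g, splits, axis=axis)):
                t._accum(gg)

        return Tensor._result(
            np.concatenate([t.data for t in parts], axis=axis), parts, backward)

    # -- gather / segment -------------------------------------------------
    def gather_rows(self, idx: np.ndarray,
                    scatter: "tuple | None" = None) -> "Tensor":
        """Select rows along axis 0 (gradient scatters back).

        `scatter` is an optional precomputed :class:`ScatterSpec` for
        `idx`: the backward scatter-add then runs as a sparse matmul,
        which is much faster than `np.add.at` on repeated indices.
        """
        a = self

        def backward(g):
            if not a.requires_grad:
                return
            if scatter is None:
                buf = np.zeros_like(a.data)
                np.add.at(buf, idx, g)
                a._accum(buf)
            else:
                a._accum(_spmm(scatter.matrix(g.dtype), g,
                               scatter.n_rows).astype(a.data.dtype, copy=False))

        return Tensor._result(a.data[idx], (a,), backward)

    def segment_sum(self, spec: "SegmentSpec") -> "Tensor":
        """Sum rows sharing a segment id; ids must be sorted ascending."""
        a = self
        out = _spmm(spec.matrix(a.data.dtype), a.data, spec.num)

        def backward(g):
            a._accum(g[spec.ids])

        return Tensor._result(out, (a,), backward)

    def spmm(self, mat: sp.csr_matrix, mat_t: sp.csr_matrix) -> "Tensor":
        """Multiply by a constant sparse matrix: out = mat @ self.

        `mat_t` must be the (precomputed) transpose of `mat`; the
        gradient is mat_t @ g.  Trailing axes are flattened through the
        product, so (N, H, F) inputs work per-channel.
        """
        a = self

        def backward(g):
            a._accum(_spmm(mat_t, g, mat_t.shape[0]))

        return Tensor._result(_spmm(mat, a.data, mat.shape[0]), (a,), backward)

    # -- losses -----------------------------------------------------------
    def cross_entropy(self, labels: np.ndarray) -> "Tensor":
        """Mean softmax cross-entropy of logit rows against integer labels."""
        a = self
        z = a.data
        m = z.max(axis=1, keepdims=True)
        ez = np.exp(z - m)
        p = ez / ez.sum(axis=1, keepdims=True)
        n = z.shape[0]
        nll = -(np.log(p[np.arange(n), labels] + 1e-300)).mean()

        def backward(g):
            gz = p.copy()
            gz[np.arange(n), labels] -= 1.0
            a._accum((g / n) * gz.astype(z.dtype))

        return Tensor._result(np.asarray(nll, dtype=z.dtype), (a,), backward)

    # -- backward ---------------------------------------------------------
    def backward(self) -> None:
        if self.data.ndim != 0:
            raise ValueError("backward() requires a scalar tensor")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


class SegmentSpec:
    """Precomputed structure for segment sums over sorted segment ids.

    `ids` maps each row to its segment; `num` is the number of segments.
    Empty segments are allowed and yield zero rows.  The reduction runs
    as a sparse (num x n_rows) selector matmul, cached per dtype.
    """

    __slots__ = ("ids", "num", "nonempty", "starts", "_mats")

    def __init__(self, segment_ids: np.ndarray, num_segments: int):
        ids = np.asarray(segment_ids)
        if ids.size and np.any(np.diff(ids) < 0):
            raise ValueError("segment ids must be sorted ascending")
        self.ids = ids
        self.num = int(num_segments)
        if ids.size:
            change = np.concatenate(([True], ids[1:] != ids[:-1]))
            self.starts = np.flatnonzero(change)
            self.nonempty = ids[self.starts]
        else:
            self.starts = np.empty(0, dtype=np.int64)
            self.nonempty = np.empty(0, dtype=np.int64)
        self._mats: dict = {}

    def matrix(self, dtype) -> sp.csr_matrix:
        key = np.dtype(dtype).str
        mat = self._mats.get(key)
        if mat is None:
            n_rows = len(self.ids)
            indptr = np.searchsorted(self.ids, np.arange(self.num + 1))
            mat = sp.csr_matrix(
                (np.ones(n_rows, dtype=dtype), np.arange(n_rows), indptr),
                shape=(self.num, n_rows))
            self._mats[key] = mat
        return mat

    def segment_max(self, values: np.ndarray) -> np.ndarray:
        """Non-differentiable per-segment max (for softmax stabilisation)."""
        out = np.full((self.num,) + values.shape[1:], -np.inf, dtype=values.dtype)
        if self.starts.size:
            out[self.nonempty] = np.maximum.reduceat(values, self.starts, axis=0)
        return out


class ScatterSpec:
    """Precomputed sparse scatter-add for a gather index vector: the
    (n_rows x len(idx)) matrix with a one at (idx[e], e)."""

    __slots__ = ("n_rows", "_perm", "_sorted", "_mats")

    def __init__(self, idx: np.ndarray, n_rows: int):
        idx = np.asarray(idx)
        self.n_rows = int(n_rows)
        self._perm = np.argsort(idx, kind="stable")
        self._sorted = idx[self._perm]
        self._mats = {}

    def matrix(self, dtype) -> sp.csr_matrix:
        key = np.dtype(dtype).str
        mat = self._mats.get(key)
        if mat is None:
            n = len(self._perm)
            indptr = np.searchsorted(self._sorted, np.arange(self.n_rows + 1))
            mat = sp.csr_matrix(
                (np.ones(n, dtype=dtype), self._perm, indptr),
                shape=(self.n_rows, n))
            self._mats[key] = mat
        return mat


class EdgeAggSpec:
    """Sparsity structure for per-head edge-weighted aggregation.

    Holds the (n x n) CSR pattern of a directed edge list sorted by
    destination, plus the data permutation that realises its transpose,
    so attention-weighted neighbour sums run as per-head sparse matmuls
    with a reusable matrix object whose data vector is swapped in place.
    """

    __slots__ = ("src", "dst", "n", "n_edges", "_indptr", "_order_t",
                 "_indptr_t", "_indices_t", "_mats", "_mats_t")

    def __init__(self, src: np.ndarray, dst: np.ndarray, n_nodes: int):
        self.src = np.asarray(src)
        self.dst = np.asarray(dst)
        if self.dst.size and np.any(np.diff(self.dst) < 0):
            raise ValueError("edges must be sorted by destination")
        self.n = int(n_nodes)
        self.n_edges = len(self.src)
        self._indptr = np.searchsorted(self.dst, np.arange(self.n + 1))
        self._order_t = np.lexsort((self.dst, self.src))
        self._indptr_t = np.searchsorted(self.src[self._order_t],
                                         np.arange(self.n + 1))
        self._indices_t = self.dst[self._order_t]
        self._mats: dict = {}
        self._mats_t: dict = {}

    def _mat(self, cache, indptr, indices, dtype) -> sp.csr_matrix:
        key = np.dtype(dtype).str
        mat = cache.get(key)
        if mat is None:
            mat = sp.csr_matrix(
                (np.zeros(self.n_edges, dtype=dtype), indices, indptr),
                shape=(self.n, self.n))
            cache[key] = mat
        return mat

    def forward_mat(self, dtype) -> sp.csr_matrix:
        return self._mat(self._mats, self._indptr, self.src, dtype)

    def transpose_mat(self, dtype) -> sp.csr_matrix:
        return self._mat(self._mats_t, self._indptr_t, self._indices_t, dtype)


def edge_weighted_matmul(weights: Tensor, feats: Tensor,
                         spec: EdgeAggSpec) -> Tensor:
    """out[d, h, :] = sum over edges (s -> d) of weights[e, h] * feats[s, h, :].

    `weights` is (E, H) on edges sorted by destination; `feats` is
    (N, H, F).  Differentiable in both arguments; the per-head products
    run as sparse matmuls on a shared CSR pattern.
    """
    e_n, n_heads = weights.data.shape
    if e_n != spec.n_edges:
        raise ValueError("weights/edge count mismatch")
    dtype = feats.data.dtype
    mat = spec.forward_mat(dtype)
    out = np.empty((spec.n, n_heads, feats.data.shape[2]), dtype=dtype)
    wd = weights.data.astype(dtype, copy=False)
    for h in range(n_heads):
        mat.data[:] = wd[:, h]
        out[:, h, :] = mat @ np.ascontiguousarray(feats.data[:, h, :])

    def backward(g):
        if weights.requires_grad:
            gw = np.einsum("ehf,ehf->eh", g[spec.dst], feats.data[spec.src])
            weights._accum(gw.astype(weights.data.dtype, copy=False))
        if feats.requires_grad:
            mat_t = spec.transpose_mat(dtype)
            wt = wd[spec._order_t]
            gf = np.empty_like(feats.data)
            for h in range(n_heads):
                mat_t.data[:] = wt[:, h]
                gf[:, h, :] = mat_t @ np.ascontiguousarray(g[:, h, :])
            feats._accum(gf)

    return Tensor._result(out, (weights, feats), backward)


class Adam:
    """Adam with decoupled-from-nothing L2: weight decay is added to the
    gradient before the moment updates (the convention of the reference
    deep-learning optimisers)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 0.01,
                 weight_decay: float = 0.0, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.wd:
                g = g + self.wd * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * (g * g)
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)
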