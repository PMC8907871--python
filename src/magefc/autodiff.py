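"""Minimal reverse-mode automatic differentiation on numpy arrays.

This engine exists to train the recurrent generator/encoder/discriminator
networks of the state-mixture model.  It implements exactly the primitives
those networks need: broadcasting arithmetic, matmul, the usual pointwise
nonlinearities, reductions, indexing/concatenation, a row-wise softmax and
a batched Gaussian negative log-likelihood with analytic gradients.

Design constraints:
  * float64 throughout (the likelihood involves log-determinants of small
    covariance matrices; single precision is not worth the risk here);
  * a ``Tensor`` wraps an ndarray and records a closed-over backward rule;
  * gradients accumulate (+=) so shared subexpressions are handled;
  * no graph retention after ``backward`` beyond what the caller holds.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "stack",
    "softmax",
    "gaussian_nll",
    "sigmoid",
    "tanh",
    "unbind_time",
    "lstm_cell",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the autodiff graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy(), requires_grad=False)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS post-order (graphs with 100-step LSTMs blow the
        # recursion limit otherwise)
        visit: list[tuple[Tensor, bool]] = [(self, False)]
        while visit:
            node, processed = visit.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            visit.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    visit.append((p, False))
        del stack
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free the closure so intermediate buffers can be reclaimed
            node._backward = None
            node._parents = ()

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return self._make(out_data, (self, other), bw)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return self._make(out_data, (self,), bw)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return self._make(out_data, (self, other), bw)

    # -- pointwise nonlinearities -----------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), bw)

    def log(self):
        out_data = np.log(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(out_data, (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out_data)

        return self._make(out_data, (self,), bw)

    # -- reductions / shaping ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        in_shape = self.data.shape

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(in_shape))

        return self._make(out_data, (self,), bw)

    def swapaxes(self, a: int, b: int):
        out_data = np.swapaxes(self.data, a, b)

        def bw(g):
            if self.requires_grad:
                self._accum(np.swapaxes(g, a, b))

        return self._make(out_data, (self,), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return self._make(out_data, (self,), bw)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        sizes = [d.shape[axis] for d in datas]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            parts = np.split(g, splits, axis=axis)
            for t, p in zip(tensors, parts):
                if t.requires_grad:
                    t._accum(p)

        out._backward = bw
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.stack([t.data for t in tensors], axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)

        def bw(g):
            parts = np.moveaxis(g, axis, 0)
            for t, p in zip(tensors, parts):
                if t.requires_grad:
                    t._accum(p)

        out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis`` with exact Jacobian."""
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s)
    if x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)

        def bw(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            x._accum(s * (g - dot))

        out._backward = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    return x.sigmoid()


def tanh(x: Tensor) -> Tensor:
    return x.tanh()


def unbind_time(x: Tensor) -> list:
    """Split (B, T, K) into T views (B, K) with slice-wise gradient writes.

    Equivalent to ``[x[:, t, :] for t in range(T)]`` but each slice's
    backward accumulates directly into the parent's gradient buffer,
    avoiding a full-size zero allocation per timestep (the recurrent
    forward pass calls this once per window).
    """
    T = x.shape[1]
    outs = []
    for t in range(T):
        out = Tensor(x.data[:, t, :])
        if x.requires_grad:
            out.requires_grad = True
            out._parents = (x,)

            def bw(g, t=t):
                if x.grad is None:
                    x.grad = np.zeros_like(x.data)
                x.grad[:, t, :] += g

            out._backward = bw
        outs.append(out)
    return outs


def lstm_cell(gates: Tensor, c_prev: Tensor) -> tuple:
    """Fused LSTM cell: pre-activation gates (B, 4H) + previous cell state.

    Returns (h_t, c_t).  Gate order is (input, forget, candidate, output).
    The fused analytic backward keeps the per-step graph at two nodes,
    which dominates the training-speed budget for long windows.
    """
    H = c_prev.data.shape[-1]
    z = gates.data
    i = 1.0 / (1.0 + np.exp(-z[:, :H]))
    f = 1.0 / (1.0 + np.exp(-z[:, H : 2 * H]))
    g = np.tanh(z[:, 2 * H : 3 * H])
    o = 1.0 / (1.0 + np.exp(-z[:, 3 * H :]))
    c = f * c_prev.data + i * g
    tc = np.tanh(c)
    h = o * tc
    out_c = Tensor(c)
    out_h = Tensor(h)
    if gates.requires_grad or c_prev.requires_grad:
        out_c.requires_grad = True
        out_h.requires_grad = True
        out_c._parents = (gates, c_prev)
        out_h._parents = (gates, out_c)

        # bw_h always runs before bw_c (out_h is a child of out_c), so the
        # output-gate gradient is stashed and folded into one fused buffer
        pending_go: list = [None]

        def bw_c(gc):
            if gates.requires_grad:
                dz = np.empty_like(z)
                dz[:, :H] = gc * g * i * (1 - i)
                dz[:, H : 2 * H] = gc * c_prev.data * f * (1 - f)
                dz[:, 2 * H : 3 * H] = gc * i * (1 - g**2)
                if pending_go[0] is not None:
                    dz[:, 3 * H :] = pending_go[0]
                else:
                    dz[:, 3 * H :] = 0.0
                gates._accum(dz)
            if c_prev.requires_grad:
                c_prev._accum(gc * f)

        def bw_h(gh):
            if gates.requires_grad:
                pending_go[0] = gh * tc * o * (1 - o)
            # chain through c (out_h is processed before out_c in reverse
            # topological order, so this accumulation is seen by bw_c)
            out_c._accum(gh * o * (1 - tc**2))

        out_c._backward = bw_c
        out_h._backward = bw_h
    return out_h, out_c


def gaussian_nll(y: np.ndarray, mean: Tensor, cov: Tensor, jitter: float = 1e-6) -> Tensor:
    """Summed negative log-likelihood of rows of ``y`` under N(mean, cov).

    ``y``: (..., N) observed data (constant), ``mean``: (..., N),
    ``cov``: (..., N, N) symmetric positive definite after ``jitter`` is
    added to the diagonal.  Gradients are the standard analytic forms
        d/dm  = -C^{-1} r,
        d/dC  = 0.5 (C^{-1} - C^{-1} r r^T C^{-1}),
    with r = y - m.
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.shape[-1]
    # symmetrize so the gradient is exact for each matrix entry independently
    C = 0.5 * (cov.data + np.swapaxes(cov.data, -1, -2)) + jitter * np.eye(n)
    L = np.linalg.cholesky(C)  # raises LinAlgError for non-PSD input
    r = y - mean.data
    # solve L z = r  ->  maha = ||z||^2
    z = np.linalg.solve(L, r[..., None])[..., 0]
    logdet = 2.0 * np.log(np.einsum("...ii->...i", L)).sum(axis=-1)
    nll = 0.5 * (logdet + (z**2).sum(axis=-1) + n * np.log(2.0 * np.pi))
    out = Tensor(nll.sum())
    if mean.requires_grad or cov.requires_grad:
        out.requires_grad = True
        out._parents = (mean, cov)

        def bw(g):
            g = float(g)
            Cinv = np.linalg.inv(C)
            Cinv_r = np.einsum("...ij,...j->...i", Cinv, r)
            if mean.requires_grad:
                mean._accum(g * (-Cinv_r))
            if cov.requires_grad:
                outer = Cinv_r[..., :, None] * Cinv_r[..., None, :]
                cov._accum(g * 0.5 * (Cinv - outer))

        out._backward = bw
    return out
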