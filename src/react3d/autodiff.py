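"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine implements exactly the operations the message-passing networks in
this package need: broadcast arithmetic, ``einsum`` contractions (the backbone
of the tensor-product convolutions), row gathering / segment reductions for
graph aggregation, a handful of pointwise nonlinearities, and an Adam
optimizer.  Everything runs in float64 so that symmetry contracts can be
asserted at tight tolerances.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "einsum",
    "concat",
    "gather",
    "segment_sum",
    "segment_mean",
    "Adam",
    "glorot",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _index_add(shape, idx, g: np.ndarray) -> np.ndarray:
    """Scatter-add rows of ``g`` into a fresh array (bincount-based; much
    faster than ``np.add.at`` for the row counts seen here)."""
    out = np.zeros(shape)
    flat_g = g.reshape(len(idx), -1)
    flat_out = out.reshape(shape[0], -1)
    for k in range(flat_g.shape[1]):
        flat_out[:, k] = np.bincount(idx, weights=flat_g[:, k],
                                     minlength=shape[0])
    return out


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad",
                 "_grad_owned")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._grad_owned = False
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in self._parents
        )

    # -- graph mechanics ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        # first contribution keeps a reference; later ones copy-on-write
        if self.grad is None:
            self.grad = g
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        out._backward = bw
        return out

    def __matmul__(self, other):
        # einsum instead of BLAS: row-wise deterministic results make
        # bitwise contracts (identical molecules -> identical rows) hold
        # regardless of where a row sits in a batch
        other = self._lift(other)
        out = Tensor(np.einsum("nk,km->nm", self.data, other.data),
                     (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(np.einsum("nm,km->nk", g, other.data))
            if other.requires_grad:
                other._accum(np.einsum("nk,nm->km", self.data, g))

        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if isinstance(idx, np.ndarray) and idx.ndim == 1 \
                    and idx.dtype == np.intp:
                self._accum(_index_add(self.shape, idx, g))
            else:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = bw
        return out

    # -- reductions and reshaping -----------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g.reshape(self.shape)
        )
        return out

    # -- pointwise nonlinearities ------------------------------------------

    def abs(self):
        out = Tensor(np.abs(self.data), (self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * np.sign(self.data)
        )
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * (1.0 - y * y)
        )
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * y * (1.0 - y)
        )
        return out

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * s, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * (s * (1.0 + self.data * (1.0 - s)))
        )
        return out

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, (self,))

        def bw(g):
            if self.requires_grad:
                dot = (g * y).sum(axis=axis, keepdims=True)
                self._accum(y * (g - dot))

        out._backward = bw
        return out


class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)

    def zero_grad(self):
        self.grad = None


# -- free functions --------------------------------------------------------


def einsum(subscripts: str, *ops: Tensor) -> Tensor:
    """Differentiable ``np.einsum``.

    Every index of each operand must appear in the output or in another
    operand (no indices summed over a single operand), which holds for all
    contractions used in this package.
    """
    in_part, out_sub = subscripts.split("->")
    in_subs = in_part.split(",")
    ops = tuple(Tensor._lift(o) for o in ops)
    for i, sub in enumerate(in_subs):
        others = out_sub + "".join(s for j, s in enumerate(in_subs) if j != i)
        if any(c not in others for c in sub):
            raise ValueError(f"unsupported einsum for autodiff: {subscripts}")
    out = Tensor(np.einsum(subscripts, *[o.data for o in ops]), ops)

    def bw(g):
        for i, op in enumerate(ops):
            if not op.requires_grad:
                continue
            rest_subs = [s for j, s in enumerate(in_subs) if j != i]
            rest_data = [o.data for j, o in enumerate(ops) if j != i]
            spec = ",".join([out_sub] + rest_subs) + "->" + in_subs[i]
            op._accum(np.einsum(spec, g, *rest_data))

    out._backward = bw
    return out


def slice_cols(t: Tensor, start: int, stop: int) -> Tensor:
    """Contiguous column slice ``t[:, start:stop]`` with cheap backward."""
    out = Tensor(t.data[:, start:stop], (t,))

    def bw(g):
        if t.requires_grad:
            full = np.zeros_like(t.data)
            full[:, start:stop] = g
            t._accum(full)

    out._backward = bw
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tensors)

    def bw(g):
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = bw
    return out


def gather(t: Tensor, idx) -> Tensor:
    """Select rows ``t[idx]`` along axis 0 (indices may repeat)."""
    return t[np.asarray(idx, dtype=np.intp)]


def segment_sum(t: Tensor, seg_ids, num_segments: int) -> Tensor:
    """Sum rows of ``t`` into ``num_segments`` buckets given per-row ids."""
    seg_ids = np.asarray(seg_ids, dtype=np.intp)
    out_data = _index_add((num_segments,) + t.data.shape[1:], seg_ids, t.data)
    out = Tensor(out_data, (t,))
    out._backward = lambda g: t.requires_grad and t._accum(g[seg_ids])
    return out


def segment_mean(t: Tensor, seg_ids, num_segments: int) -> Tensor:
    """Mean of rows per segment; empty segments yield zero rows."""
    seg_ids = np.asarray(seg_ids, dtype=np.intp)
    counts = np.bincount(seg_ids, minlength=num_segments).astype(float)
    counts = np.maximum(counts, 1.0)
    s = segment_sum(t, seg_ids, num_segments)
    shape = (num_segments,) + (1,) * (t.ndim - 1)
    return s * (1.0 / counts.reshape(shape))


class Adam:
    """Adam optimizer with optional (coupled) L2 weight decay."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
           shape=None) -> np.ndarray:
    """Glorot-uniform initial weights."""
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return rng.uniform(-lim, lim, size=shape)
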