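"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just the operations the binding model needs: broadcast arithmetic,
(batched) matmul, two-operand einsum, row gathering, sliding windows,
relu/sigmoid, axis max/sum, batch normalization, and dropout.  Gradients
are accumulated by a topological backward sweep over the recorded graph.

The einsum gradient uses the standard identity for two-operand
contractions in which no index repeats within an operand and every index
of each operand also appears in the output or the other operand —
grad_a = einsum("<out>,<b> -> <a>", grad, b) — which holds for every
subscript string used in this package.
"""

from __future__ import annotations

import numpy as np

#: Working precision of every Tensor.  float32 is plenty for training and
#: halves memory traffic; switch to float64 (before building a model) for
#: finite-difference gradient checking.
DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # operator sugar
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return add(self, mul_const(_as_tensor(other), -1.0))

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def zero_grad(self):
        self.grad = None

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def mul_const(a: Tensor, c: float) -> Tensor:
    data = a.data * c

    def backward(g):
        a._accumulate(g * c)

    return _make(data, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """np.matmul semantics incl. batched leading dimensions."""
    data = np.matmul(a.data, b.data)

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        a._accumulate(_unbroadcast(ga, a.data.shape))
        b._accumulate(_unbroadcast(gb, b.data.shape))

    return _make(data, (a, b), backward)


def einsum2(spec: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum; see module docstring for the gradient identity."""
    lhs, out_spec = spec.replace(" ", "").split("->")
    a_spec, b_spec = lhs.split(",")
    data = np.einsum(spec, a.data, b.data, optimize=True)

    def backward(g):
        ga = np.einsum(f"{out_spec},{b_spec}->{a_spec}", g, b.data, optimize=True)
        gb = np.einsum(f"{out_spec},{a_spec}->{b_spec}", g, a.data, optimize=True)
        a._accumulate(ga)
        b._accumulate(gb)

    return _make(data, (a, b), backward)


def relu(a: Tensor) -> Tensor:
    data = np.maximum(a.data, 0.0)

    def backward(g):
        a._accumulate(g * (a.data > 0))

    return _make(data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accumulate(g * data * (1.0 - data))

    return _make(data, (a,), backward)


def reshape(a: Tensor, shape) -> Tensor:
    data = a.data.reshape(shape)

    def backward(g):
        a._accumulate(g.reshape(a.data.shape))

    return _make(data, (a,), backward)


def transpose(a: Tensor, axes) -> Tensor:
    data = np.transpose(a.data, axes)
    inv = np.argsort(axes)

    def backward(g):
        a._accumulate(np.transpose(g, inv))

    return _make(data, (a,), backward)


def take(a: Tensor, indices: np.ndarray) -> Tensor:
    """Gather rows along axis 0; scatter-add on the way back.

    The backward pass groups duplicate indices with a sort +
    ``np.add.reduceat`` sweep, which is far faster than ``np.add.at``
    for the embedding/kernel gathers this package performs.
    """
    indices = np.asarray(indices, dtype=np.int64)
    data = a.data[indices]

    def backward(g):
        acc = np.zeros_like(a.data)
        uniq, inv = np.unique(indices, return_inverse=True)
        inv = np.asarray(inv).ravel()
        if len(uniq) == len(indices):  # permutation/subset: plain scatter
            acc[indices] = g
        else:
            order = np.argsort(inv, kind="stable")
            flat = g.reshape(len(indices), -1)[order]
            bounds = np.concatenate(([0], np.cumsum(np.bincount(inv))[:-1]))
            sums = np.add.reduceat(flat, bounds, axis=0)
            acc[uniq] = sums.reshape((len(uniq),) + g.shape[1:])
        a._accumulate(acc)

    return _make(data, (a,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return _make(data, tuple(tensors), backward)


def windows(a: Tensor, size: int) -> Tensor:
    """Sliding windows over axis 1: (B, L, d) -> (B, L-size+1, size, d)."""
    B, L, d = a.data.shape
    J = L - size + 1
    data = np.lib.stride_tricks.sliding_window_view(a.data, size, axis=1)
    # view comes out as (B, J, d, size); reorder to (B, J, size, d)
    data = np.ascontiguousarray(np.transpose(data, (0, 1, 3, 2)))

    def backward(g):
        acc = np.zeros_like(a.data)
        for j in range(J):
            acc[:, j : j + size, :] += g[:, j, :, :]
        a._accumulate(acc)

    return _make(data, (a,), backward)


def amax(a: Tensor, axis: int) -> Tensor:
    """Max over one axis; ties send the gradient to the first maximizer."""
    data = np.max(a.data, axis=axis)
    idx = np.argmax(a.data, axis=axis)

    def backward(g):
        acc = np.zeros_like(a.data)
        np.put_along_axis(
            acc, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis
        )
        a._accumulate(acc)

    return _make(data, (a,), backward)


def mean(a: Tensor) -> Tensor:
    n = a.data.size
    data = np.array(a.data.mean())

    def backward(g):
        a._accumulate(np.full_like(a.data, float(g) / n))

    return _make(data, (a,), backward)


def dropout(a: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; call only in training mode."""
    if rate <= 0:
        return a
    mask = (rng.random(a.data.shape) >= rate) / (1.0 - rate)
    return mul(a, Tensor(mask))


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalization over axis 0 of a (N, C) tensor.

    Training mode normalizes with batch statistics and updates the
    running estimates in place; eval mode uses the running estimates and
    is deterministic.
    """
    if training:
        mu = x.data.mean(axis=0)
        var = x.data.var(axis=0)
        n = x.data.shape[0]
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        # unbiased estimate feeds the running variance, as is conventional
        running_var += momentum * (var * n / max(n - 1, 1))
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    data = gamma.data * xhat + beta.data

    def backward(g):
        gamma._accumulate((g * xhat).sum(axis=0))
        beta._accumulate(g.sum(axis=0))
        gxhat = g * gamma.data
        if training:
            n = x.data.shape[0]
            gx = (
                gxhat
                - gxhat.mean(axis=0)
                - xhat * (gxhat * xhat).mean(axis=0)
            ) * inv_std
        else:
            gx = gxhat * inv_std
        x._accumulate(gx)

    return _make(data, (x, gamma, beta), backward)
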