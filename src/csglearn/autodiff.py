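"""Compact reverse-mode automatic differentiation over NumPy float64 arrays.

The whole model (molecule encoders, synthesis-graph attention, margin loss)
is expressed with :class:`Tensor` operations, so a single ``backward()`` call
yields exact gradients for every registered parameter.  The op set is the
minimum the model needs: broadcast arithmetic, dense and sparse matmul, a few
pointwise nonlinearities, row gather/scatter and contiguous-segment reductions.

Design notes
------------
* float64 throughout: runs are bit-reproducible for a fixed seed and the
  finite-difference gradient checks in the test-suite are meaningful.
* ``sqrt0`` is a *safe* square root whose subgradient at 0 is defined as 0.
  Euclidean distances built from it are exact (no epsilon shift), which keeps
  hand-evaluated loss values exact as well; the kink at 0 is a measure-zero
  event during training.
* Segment reductions assume items of a segment are contiguous (the batched
  molecular graphs are laid out that way); general scatter goes through
  sparse-matrix products.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Tensor",
    "concat",
    "spmm",
    "segment_max",
    "Adam",
    "glorot_uniform",
    "finite_difference_grad",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node of the autodiff graph wrapping an ``ndarray`` value."""

    __slots__ = ("data", "grad", "_parents", "_bw")

    def __init__(self, data, _parents: tuple = (), _bw: Callable | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._bw = _bw

    # ------------------------------------------------------------------ meta
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, grad={'set' if self.grad is not None else 'none'})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, (self, other))
        out._bw = lambda g: (
            _unbroadcast(g, self.data.shape),
            _unbroadcast(g, other.data.shape),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._bw = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, (self, other))
        out._bw = lambda g: (
            _unbroadcast(g * other.data, self.data.shape),
            _unbroadcast(g * self.data, other.data.shape),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, (self, other))
        out._bw = lambda g: (
            _unbroadcast(g / other.data, self.data.shape),
            _unbroadcast(-g * self.data / other.data**2, other.data.shape),
        )
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, (self,))
        out._bw = lambda g: (g * p * self.data ** (p - 1),)
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, (self, other))
        out._bw = lambda g: (g @ other.data.T, self.data.T @ g)
        return out

    # ----------------------------------------------------------- structural
    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), (self,))
        out._bw = lambda g: (g.reshape(orig),)
        return out

    @property
    def T(self):
        out = Tensor(self.data.T, (self,))
        out._bw = lambda g: (g.T,)
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            full[key] = g
            return (full,)

        out._bw = bw
        return out

    def gather_rows(self, idx: np.ndarray):
        """Row lookup ``self[idx]`` with scatter-add backward."""
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(self.data[idx], (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        out._bw = bw
        return out

    # ------------------------------------------------------------ pointwise
    def relu(self):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), (self,))
        out._bw = lambda g: (g * mask,)
        return out

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, slope * self.data), (self,))
        out._bw = lambda g: (g * np.where(mask, 1.0, slope),)
        return out

    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, (self,))
        out._bw = lambda g: (g * val,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))
        out._bw = lambda g: (g / self.data,)
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, (self,))
        out._bw = lambda g: (g * (1.0 - val**2),)
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(val, (self,))
        out._bw = lambda g: (g * val * (1.0 - val),)
        return out

    def sqrt0(self):
        """Square root with subgradient 0 at 0 (exact at zero residuals)."""
        val = np.sqrt(np.maximum(self.data, 0.0))
        out = Tensor(val, (self,))

        def bw(g):
            with np.errstate(divide="ignore"):
                d = np.where(val > 0.0, 0.5 / np.where(val > 0.0, val, 1.0), 0.0)
            return (g * d,)

        out._bw = bw
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.data.shape).copy(),)

        out._bw = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._bw is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._bw(node.grad)):
                if g is None:
                    continue
                parent.grad = g if parent.grad is None else parent.grad + g


# ---------------------------------------------------------------- free ops
def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    out._bw = bw
    return out


def spmm(mat: sp.spmatrix, x: Tensor) -> Tensor:
    """Constant sparse matrix times tensor: ``mat @ x``."""
    mat = mat.tocsr()
    out = Tensor(mat @ x.data, (x,))
    mat_t = mat.T.tocsr()
    out._bw = lambda g: (mat_t @ g,)
    return out


def segment_max(x: Tensor, starts: np.ndarray) -> Tensor:
    """Row-wise max over contiguous segments given by ``starts`` offsets."""
    starts = np.asarray(starts, dtype=np.intp)
    n_seg = len(starts)
    bounds = np.append(starts, x.data.shape[0])
    val = np.maximum.reduceat(x.data, starts, axis=0)
    out = Tensor(val, (x,))

    def bw(g):
        full = np.zeros_like(x.data)
        for s in range(n_seg):
            a, b = bounds[s], bounds[s + 1]
            am = np.argmax(x.data[a:b], axis=0)
            full[a + am, np.arange(x.data.shape[1])] += g[s]
        return (full,)

    out._bw = bw
    return out


# ---------------------------------------------------------------- training
def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = shape[0] if len(shape) > 1 else shape[0]
    fan_out = shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam optimizer over a named parameter dict of :class:`Tensor`."""

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, p in self.params.items():
            if p.grad is None:
                continue
            m = self._m[name] = b1 * self._m[name] + (1 - b1) * p.grad
            v = self._v[name] = b2 * self._v[name] + (1 - b2) * p.grad**2
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def finite_difference_grad(
    f: Callable[[], Tensor], param: Tensor, eps: float = 1e-6
) -> np.ndarray:
    """Central finite-difference gradient of scalar ``f()`` w.r.t. ``param``."""
    grad = np.zeros_like(param.data)
    it = np.nditer(param.data, flags=["multi_index"])
    while not it.finished:
        ix = it.multi_index
        orig = param.data[ix]
        param.data[ix] = orig + eps
        hi = f().item()
        param.data[ix] = orig - eps
        lo = f().item()
        param.data[ix] = orig
        grad[ix] = (hi - lo) / (2 * eps)
        it.iternext()
    return grad
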