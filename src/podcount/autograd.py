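"""A small reverse-mode automatic-differentiation engine on numpy arrays.

The package trains its detector with plain numpy, so this module provides
the minimal tensor/op set the model needs: broadcasting arithmetic, matmul,
im2col convolution, same-size max pooling, nearest upsampling, reductions,
stable sigmoid / log-softmax / binary cross-entropy, and fancy indexing.
Gradients are accumulated through a topologically sorted backward pass.

Everything is float32 by default. A process-wide "mixed precision" switch
emulates half-precision storage by rounding matmul/convolution operands
through float16 while accumulating in float32.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "trace_ops",
    "set_mixed_precision",
    "mixed_precision_enabled",
]

_GRAD_ENABLED = True
_MIXED = False

# op-cost tracing used by the analytic FLOP counter: when enabled, every
# conv/matmul records multiply-accumulates and every sigmoid/SiLU records
# its element count
_TRACE: Optional[dict] = None


@contextlib.contextmanager
def trace_ops():
    """Collect {'macs': int, 'act_elems': int} over the enclosed forward."""
    global _TRACE
    prev, _TRACE = _TRACE, {"macs": 0, "act_elems": 0}
    try:
        yield _TRACE
    finally:
        _TRACE = prev


def _trace_macs(n: int) -> None:
    if _TRACE is not None:
        _TRACE["macs"] += int(n)


def _trace_act(n: int) -> None:
    if _TRACE is not None:
        _TRACE["act_elems"] += int(n)


@contextlib.contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev, _GRAD_ENABLED = _GRAD_ENABLED, False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def set_mixed_precision(enabled: bool) -> None:
    global _MIXED
    _MIXED = bool(enabled)


def mixed_precision_enabled() -> bool:
    return _MIXED


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    """Overflow-free logistic function."""
    e = np.exp(-np.abs(x))
    return np.where(x >= 0, 1.0 / (1.0 + e), e / (1.0 + e))


def _half(a: np.ndarray) -> np.ndarray:
    """Round through float16 when mixed precision is on."""
    if _MIXED:
        return a.astype(np.float16).astype(np.float32)
    return a


ArrayLike = Union["Tensor", np.ndarray, float, int]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: Sequence["Tensor"] = (),
        _backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._parents = tuple(_parents) if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- basic plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without grad on non-scalar")
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _wrap(x: ArrayLike) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    @staticmethod
    def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
        """Sum gradient over axes that were broadcast in the forward op."""
        if g.shape == shape:
            return g
        extra = g.ndim - len(shape)
        if extra > 0:
            g = g.sum(axis=tuple(range(extra)))
        axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
        if axes:
            g = g.sum(axis=axes, keepdims=True)
        return g.reshape(shape)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other: ArrayLike) -> "Tensor":
        other = self._wrap(other)
        out_data = self.data + other.data
        req = self.requires_grad or other.requires_grad

        def backward(g):
            if self.requires_grad:
                self._accumulate(self._unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(self._unbroadcast(g, other.data.shape))

        return Tensor(out_data, req, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g):
            self._accumulate(-g)

        return Tensor(-self.data, self.requires_grad, (self,), backward)

    def __sub__(self, other: ArrayLike) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other: ArrayLike) -> "Tensor":
        return self._wrap(other) + (-self)

    def __mul__(self, other: ArrayLike) -> "Tensor":
        other = self._wrap(other)
        out_data = self.data * other.data
        req = self.requires_grad or other.requires_grad

        def backward(g):
            if self.requires_grad:
                self._accumulate(self._unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(self._unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, req, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other: ArrayLike) -> "Tensor":
        other = self._wrap(other)
        out_data = self.data / other.data
        req = self.requires_grad or other.requires_grad

        def backward(g):
            if self.requires_grad:
                self._accumulate(self._unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    self._unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor(out_data, req, (self, other), backward)

    def __rtruediv__(self, other: ArrayLike) -> "Tensor":
        return self._wrap(other) / self

    def pow(self, p: float) -> "Tensor":
        out_data = self.data**p

        def backward(g):
            self._accumulate(g * p * self.data ** (p - 1))

        return Tensor(out_data, self.requires_grad, (self,), backward)

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return Tensor(out_data, self.requires_grad, (self,), backward)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def backward(g):
            self._accumulate(g / self.data)

        return Tensor(out_data, self.requires_grad, (self,), backward)

    # -- comparisons with subgradients ------------------------------------

    def maximum(self, other: ArrayLike) -> "Tensor":
        other = self._wrap(other)
        out_data = np.maximum(self.data, other.data)
        req = self.requires_grad or other.requires_grad
        mask = self.data >= other.data  # ties route to self

        def backward(g):
            if self.requires_grad:
                self._accumulate(self._unbroadcast(g * mask, self.data.shape))
            if other.requires_grad:
                other._accumulate(self._unbroadcast(g * (~mask), other.data.shape))

        return Tensor(out_data, req, (self, other), backward)

    def minimum(self, other: ArrayLike) -> "Tensor":
        other = self._wrap(other)
        out_data = np.minimum(self.data, other.data)
        req = self.requires_grad or other.requires_grad
        mask = self.data <= other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(self._unbroadcast(g * mask, self.data.shape))
            if other.requires_grad:
                other._accumulate(self._unbroadcast(g * (~mask), other.data.shape))

        return Tensor(out_data, req, (self, other), backward)

    def relu(self) -> "Tensor":
        return self.maximum(0.0)

    def clip(self, lo: float, hi: float) -> "Tensor":
        return self.maximum(lo).minimum(hi)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        orig = self.data.shape

        def backward(g):
            self._accumulate(g.reshape(orig))

        return Tensor(out_data, self.requires_grad, (self,), backward)

    def flatten_from(self, axis: int) -> "Tensor":
        lead = self.data.shape[:axis]
        return self.reshape(*lead, -1)

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]
        fancy = isinstance(idx, np.ndarray) or (
            isinstance(idx, tuple) and any(isinstance(i, np.ndarray) for i in idx)
        )

        def backward(g):
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            if fancy:
                np.add.at(self.grad, idx, g)
            else:
                self.grad[idx] += g

        return Tensor(out_data, self.requires_grad, (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(inv))

        return Tensor(out_data, self.requires_grad, (self,), backward)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, shape).copy())
                return
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, axes)
            self._accumulate(np.broadcast_to(g, shape).copy())

        return Tensor(out_data, self.requires_grad, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: Union[int, tuple], keepdims: bool = False) -> "Tensor":
        axes = axis if isinstance(axis, tuple) else (axis,)
        out_data = self.data.max(axis=axes, keepdims=keepdims)
        expanded = self.data.max(axis=axes, keepdims=True)
        mask = self.data == expanded
        counts = mask.sum(axis=axes, keepdims=True)

        def backward(g):
            if not keepdims:
                g = np.expand_dims(g, axes)
            self._accumulate(mask * (g / counts))

        return Tensor(out_data, self.requires_grad, (self,), backward)

    # -- linear algebra ----------------------------------------------------

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        a, b = _half(self.data), _half(other.data)
        out_data = a @ b
        _trace_macs(out_data.size * a.shape[-1])
        req = self.requires_grad or other.requires_grad

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ b.T)
            if other.requires_grad:
                other._accumulate(a.T @ g)

        return Tensor(out_data, req, (self, other), backward)

    def __matmul__(self, other):
        return self.matmul(other)

    # -- fused nonlinearities ---------------------------------------------

    def sigmoid(self) -> "Tensor":
        x = self.data
        out_data = _stable_sigmoid(x)
        _trace_act(out_data.size)

        def backward(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor(out_data.astype(np.float32), self.requires_grad, (self,), backward)

    def silu(self) -> "Tensor":
        s = self.sigmoid().data
        out_data = self.data * s

        def backward(g):
            self._accumulate(g * (s + self.data * s * (1.0 - s)))

        return Tensor(out_data, self.requires_grad, (self,), backward)

    def log_softmax(self, axis: int = -1) -> "Tensor":
        """Numerically stable log-softmax along ``axis``."""
        if not np.all(np.isfinite(self.data)):
            raise ValueError("log_softmax: non-finite logits")
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out_data = shifted - lse
        softmax = np.exp(out_data)

        def backward(g):
            self._accumulate(g - softmax * g.sum(axis=axis, keepdims=True))

        return Tensor(out_data, self.requires_grad, (self,), backward)

    def bce_with_logits(self, target: np.ndarray) -> "Tensor":
        """Elementwise stable binary cross-entropy against constant targets."""
        x, t = self.data, np.asarray(target, dtype=np.float32)
        out_data = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))
        sig = _stable_sigmoid(x)

        def backward(g):
            self._accumulate(g * (sig - t).astype(np.float32))

        return Tensor(out_data.astype(np.float32), self.requires_grad, (self,), backward)


# -- spatial ops (NCHW) ----------------------------------------------------


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Optional[Tensor],
    stride: int = 1,
    padding: int = 0,
) -> Tensor:
    """2-D convolution via im2col; NCHW activations, (F, C, kh, kw) weights."""
    N, C, H, W = x.data.shape
    F, Cw, kh, kw = w.data.shape
    assert C == Cw, f"channel mismatch {C} vs {Cw}"
    xp = x.data
    if padding:
        xp = np.pad(
            xp, ((0, 0), (0, 0), (padding, padding), (padding, padding))
        )
    Hp, Wp = xp.shape[2], xp.shape[3]
    oh = (Hp - kh) // stride + 1
    ow = (Wp - kw) // stride + 1
    sN, sC, sH, sW = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp,
        shape=(N, C, kh, kw, oh, ow),
        strides=(sN, sC, sH, sW, sH * stride, sW * stride),
        writeable=False,
    )
    cols = _half(
        np.ascontiguousarray(view.transpose(0, 4, 5, 1, 2, 3)).reshape(
            N * oh * ow, C * kh * kw
        )
    )
    wmat = _half(w.data.reshape(F, -1).T)  # (C*kh*kw, F)
    out = cols @ wmat
    _trace_macs(out.size * cols.shape[-1])
    if b is not None:
        out = out + b.data
        _trace_macs(out.size)
    out_data = out.reshape(N, oh, ow, F).transpose(0, 3, 1, 2)
    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(N * oh * ow, F)
        if w.requires_grad:
            w._accumulate((cols.T @ gmat).T.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(gmat.sum(axis=0))
        if x.requires_grad:
            dcols = (gmat @ wmat.T).reshape(N, oh, ow, C, kh, kw)
            dxp = np.zeros((N, C, Hp, Wp), dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += (
                        dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                    )
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, req, parents, backward)


def max_pool_same(x: Tensor, k: int) -> Tensor:
    """Max pooling, stride 1, odd kernel, output size preserved."""
    assert k % 2 == 1
    p = k // 2
    N, C, H, W = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    flat = win.reshape(N, C, H, W, k * k)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        gp = np.zeros_like(xp, dtype=np.float32)
        di, dj = np.unravel_index(arg, (k, k))
        ii = np.arange(H)[None, None, :, None] + di
        jj = np.arange(W)[None, None, None, :] + dj
        nn = np.arange(N)[:, None, None, None]
        cc = np.arange(C)[None, :, None, None]
        np.add.at(gp, (nn, cc, ii, jj), g)
        x._accumulate(gp[:, :, p : p + H, p : p + W])

    return Tensor(out_data.astype(np.float32), x.requires_grad, (x,), backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    N, C, H, W = x.data.shape
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        x._accumulate(g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

    return Tensor(out_data, x.requires_grad, (x,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    sizes = [t.data.shape[axis] for t in tensors]

    def backward(g):
        pieces = np.split(g, np.cumsum(sizes)[:-1], axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor(out_data, req, tuple(tensors), backward)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    return Tensor(out_data, req, tuple(tensors), backward)


def space_to_depth2(x: Tensor) -> Tensor:
    """Rearrange (N, C, 2H, 2W) -> (N, 4C, H, W) by 2x2 pixel-unshuffle."""
    N, C, H, W = x.data.shape
    assert H % 2 == 0 and W % 2 == 0
    parts = [
        x[:, :, 0::2, 0::2],
        x[:, :, 1::2, 0::2],
        x[:, :, 0::2, 1::2],
        x[:, :, 1::2, 1::2],
    ]
    return concat(parts, axis=1)
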