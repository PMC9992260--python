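"""A small reverse-mode automatic differentiation engine on numpy arrays.

The engine is tape-free: every operation builds a node holding a backward
closure, and :meth:`Tensor.backward` runs an iterative topological sweep.
Only the operations the reconstruction networks need are provided —
broadcast arithmetic, matmul, stride-1 grouped 2-D convolution, pooling by
reshape, nearest-neighbour upsampling, reflect padding, slicing/concat,
sigmoid/SiLU, and centred orthonormal 2-D FFTs on (real, imaginary) channel
pairs.  Arrays keep whatever float dtype they come in with (float32 for
training, float64 for gradient checks).
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "concat",
    "stack_pair",
    "matmul",
    "conv2d",
    "upsample_nearest2",
    "reflect_pad2d",
    "sigmoid",
    "silu",
    "fft2c_pair",
    "ifft2c_pair",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (the reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(self, data, requires_grad: bool = False, dtype=None):
        arr = np.asarray(data, dtype=dtype)
        if arr.dtype.kind != "f":
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._prev: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative topological order over grad-requiring subgraph
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self.grad = grad if self.grad is None else self.grad + grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_as_tensor(other, self.dtype))

    def __rsub__(self, other):
        return add(_as_tensor(other, self.dtype), -self)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / other)

    def __rtruediv__(self, other):
        return mul(power(self, -1.0), other)

    def __pow__(self, e):
        return power(self, e)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def sqrt(self):
        return power(self, 0.5)

    def abs(self):
        return tabs(self)

    def exp(self):
        return texp(self)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def _node(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._prev = tuple(parents)
        out._backward = backward
    return out


def _acc(t: Tensor, g: np.ndarray) -> None:
    if t.requires_grad:
        g = _unbroadcast(g, t.data.shape)
        t.grad = g if t.grad is None else t.grad + g


# -- arithmetic -----------------------------------------------------------

def add(a, b) -> Tensor:
    a = _as_tensor(a)
    b = _as_tensor(b, a.dtype)
    out_data = a.data + b.data

    def backward(g):
        _acc(a, g)
        _acc(b, g)

    return _node(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a = _as_tensor(a)
    b = _as_tensor(b, a.dtype)
    out_data = a.data * b.data

    def backward(g):
        _acc(a, g * b.data)
        _acc(b, g * a.data)

    return _node(out_data, (a, b), backward)


def power(a: Tensor, e: float) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data ** e

    def backward(g):
        _acc(a, g * e * a.data ** (e - 1.0))

    return _node(out_data, (a,), backward)


def texp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def backward(g):
        _acc(a, g * out_data)

    return _node(out_data, (a,), backward)


def tabs(a: Tensor) -> Tensor:
    out_data = np.abs(a.data)

    def backward(g):
        _acc(a, g * np.sign(a.data))

    return _node(out_data, (a,), backward)


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        _acc(a, np.broadcast_to(g, a.data.shape).copy())

    return _node(out_data, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in np.atleast_1d(axis)]
    )
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


def reshape(a: Tensor, shape) -> Tensor:
    orig = a.data.shape
    out_data = a.data.reshape(shape)

    def backward(g):
        _acc(a, g.reshape(orig))

    return _node(out_data, (a,), backward)


def getitem(a: Tensor, idx) -> Tensor:
    out_data = a.data[idx]

    def backward(g):
        full = np.zeros_like(a.data)
        full[idx] += g
        _acc(a, full)

    return _node(out_data, (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, offsets, axis=axis)
        for t, piece in zip(ts, pieces):
            _acc(t, piece)

    return _node(out_data, tuple(ts), backward)


def stack_pair(re: Tensor, im: Tensor, axis: int = -3) -> Tensor:
    """Stack real/imaginary parts into a pair channel axis."""
    return concat([_expand(re, axis), _expand(im, axis)], axis=axis)


def _expand(t: Tensor, axis: int) -> Tensor:
    shape = list(t.data.shape)
    ax = axis if axis >= 0 else t.ndim + 1 + axis
    shape.insert(ax, 1)
    return reshape(t, tuple(shape))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        _acc(a, g @ b.data.T)
        _acc(b, a.data.T @ g)

    return _node(out_data, (a, b), backward)


# -- activations ----------------------------------------------------------

def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        _acc(a, g * s * (1.0 - s))

    return _node(s, (a,), backward)


def silu(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))
    out_data = a.data * s

    def backward(g):
        _acc(a, g * (s + a.data * s * (1.0 - s)))

    return _node(out_data, (a,), backward)


# -- convolution ----------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int) -> np.ndarray:
    # xp: [N, C, Hp, Wp] zero-padded; returns [N, C, Ho, Wo, kh, kw] view
    return np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           padding: int = 0, groups: int = 1) -> Tensor:
    """Stride-1 grouped 2-D convolution (cross-correlation), NCHW layout."""
    n, cin, h, wd = x.data.shape
    cout, cin_g, kh, kw = w.data.shape
    if cin % groups or cout % groups or cin // groups != cin_g:
        raise ValueError(
            f"channel/group mismatch: x has {cin} channels, weight expects "
            f"{cin_g}×{groups} in {groups} groups"
        )
    pad = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    cols = _im2col(xp, kh, kw)  # [N, Cin, Ho, Wo, kh, kw]
    ho, wo = cols.shape[2], cols.shape[3]
    cpg_out = cout // groups
    out = np.empty((n, cout, ho, wo), dtype=x.data.dtype)
    for g in range(groups):
        cs, ce = g * cin_g, (g + 1) * cin_g
        os, oe = g * cpg_out, (g + 1) * cpg_out
        out[:, os:oe] = np.einsum(
            "nchwij,ocij->nohw", cols[:, cs:ce], w.data[os:oe], optimize=True
        )
    if b is not None:
        out += b.data.reshape(1, cout, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(gout):
        if b is not None and b.requires_grad:
            _acc(b, gout.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for g in range(groups):
                cs, ce = g * cin_g, (g + 1) * cin_g
                os, oe = g * cpg_out, (g + 1) * cpg_out
                gw[os:oe] = np.einsum(
                    "nchwij,nohw->ocij", cols[:, cs:ce], gout[:, os:oe],
                    optimize=True,
                )
            _acc(w, gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for g in range(groups):
                cs, ce = g * cin_g, (g + 1) * cin_g
                os, oe = g * cpg_out, (g + 1) * cpg_out
                # distribute grad through each kernel tap
                contrib = np.einsum(
                    "nohw,ocij->nchwij", gout[:, os:oe], w.data[os:oe],
                    optimize=True,
                )
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, cs:ce, i:i + ho, j:j + wo] += contrib[..., i, j]
            gx = gxp[:, :, pad:pad + h, pad:pad + wd] if pad else gxp
            _acc(x, gx)

    return _node(out, parents, backward)


def upsample_nearest2(x: Tensor) -> Tensor:
    """Nearest-neighbour ×2 upsampling on the last two dims (NCHW)."""
    out_data = np.repeat(np.repeat(x.data, 2, axis=-2), 2, axis=-1)

    def backward(g):
        n, c, h2, w2 = g.shape
        _acc(x, g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    return _node(out_data, (x,), backward)


def reflect_pad2d(x: Tensor, pads: tuple[int, int, int, int]) -> Tensor:
    """Reflect-pad the last two dims by (top, bottom, left, right)."""
    pt, pb, pl, pr = pads
    if pt == pb == pl == pr == 0:
        return x
    h, w = x.data.shape[-2:]
    spec = [(0, 0)] * (x.ndim - 2) + [(pt, pb), (pl, pr)]
    out_data = np.pad(x.data, spec, mode="reflect")
    idx = np.pad(np.arange(h * w).reshape(h, w),
                 [(pt, pb), (pl, pr)], mode="reflect").ravel()

    def backward(g):
        lead = g.shape[:-2]
        gflat = g.reshape(*lead, -1)
        acc = np.zeros(lead + (h * w,), dtype=g.dtype)
        np.add.at(acc, (..., idx), gflat)
        _acc(x, acc.reshape(x.data.shape))

    return _node(out_data, (x,), backward)


# -- centred orthonormal FFTs on (re, im) channel pairs -------------------

def _pair_to_complex(arr: np.ndarray) -> np.ndarray:
    return arr[..., 0, :, :] + 1j * arr[..., 1, :, :]


def _complex_to_pair(c: np.ndarray, dtype) -> np.ndarray:
    return np.stack([c.real, c.imag], axis=-3).astype(dtype)


def _fft2c_np(c: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(c, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


def _ifft2c_np(c: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(c, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


def fft2c_pair(x: Tensor) -> Tensor:
    """Centred orthonormal 2-D FFT; axis -3 holds (real, imaginary).

    The transform is unitary, so the vector-Jacobian product is the inverse
    transform applied to the cotangent pair.
    """
    out_data = _complex_to_pair(_fft2c_np(_pair_to_complex(x.data)), x.dtype)

    def backward(g):
        _acc(x, _complex_to_pair(_ifft2c_np(_pair_to_complex(g)), x.dtype))

    return _node(out_data, (x,), backward)


def ifft2c_pair(x: Tensor) -> Tensor:
    out_data = _complex_to_pair(_ifft2c_np(_pair_to_complex(x.data)), x.dtype)

    def backward(g):
        _acc(x, _complex_to_pair(_fft2c_np(_pair_to_complex(g)), x.dtype))

    return _node(out_data, (x,), backward)
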