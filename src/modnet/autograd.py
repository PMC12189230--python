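"""Reverse-mode automatic differentiation on NumPy arrays.

A small define-by-run engine: every operation on :class:`Tensor` records a
backward closure, and :meth:`Tensor.backward` walks the graph in reverse
topological order.  Arrays are kept in float64 throughout; the feature maps
this package pushes through it are small enough that double precision costs
little and keeps the analytic-identity tests comfortably inside their
tolerances.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "maxpool2d",
    "fft2_stack",
    "ifft2_real",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (the reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    """An n-d array plus the machinery to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad = self.grad + g

    # -- graph ----------------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative post-order DFS; recursion would overflow on deep nets
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._wrap(other)
        out = _node(self.data + other.data, (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g, other.data.shape))
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        out = _node(self.data * other.data, (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g * other.data, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g * self.data, other.data.shape))
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        out = _node(self.data ** p, (self,))
        if out.requires_grad:
            def bw(g):
                self._accum(g * p * self.data ** (p - 1.0))
            out._backward = bw
        return out

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        out = _node(self.data @ other.data, (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                    self._accum(_unbroadcast(ga, self.data.shape))
                if other.requires_grad:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                    other._accum(_unbroadcast(gb, other.data.shape))
            out._backward = bw
        return out

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self):
        out = _node(np.maximum(self.data, 0.0), (self,))
        if out.requires_grad:
            mask = self.data > 0
            out._backward = lambda g: self._accum(g * mask)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = _node(s, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def exp(self):
        e = np.exp(self.data)
        out = _node(e, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * e)
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g / self.data)
        return out

    def clamp_min(self, v: float):
        out = _node(np.maximum(self.data, v), (self,))
        if out.requires_grad:
            mask = self.data > v
            out._backward = lambda g: self._accum(g * mask)
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            def bw(g):
                gg = g
                if not keepdims and axis is not None:
                    gg = np.expand_dims(gg, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis, keepdims: bool = False):
        """Max reduction; ties share the gradient equally (a valid subgradient)."""
        m = self.data.max(axis=axis, keepdims=True)
        out_data = m if keepdims else np.squeeze(m, axis=axis)
        out = _node(out_data, (self,))
        if out.requires_grad:
            mask = (self.data == m).astype(np.float64)
            mask /= mask.sum(axis=axis, keepdims=True)
            def bw(g):
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(mask * gg)
            out._backward = bw
        return out

    # -- shaping --------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _node(self.data.reshape(shape), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, axes):
        out = _node(self.data.transpose(axes), (self,))
        if out.requires_grad:
            inv = np.argsort(axes)
            out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = _node(self.data[idx], (self,))
        if out.requires_grad:
            def bw(g):
                # basic (slice) indexing only: no duplicated positions,
                # so in-place add is the correct scatter
                full = np.zeros_like(self.data)
                full[idx] += g
                self._accum(full)
            out._backward = bw
        return out


def _node(data: np.ndarray, prev: tuple[Tensor, ...]) -> Tensor:
    t = Tensor(data)
    t.requires_grad = any(p.requires_grad for p in prev)
    if t.requires_grad:
        t._prev = prev
    return t


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)
        def bw(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(a, b)
                    t._accum(g[tuple(sl)])
        out._backward = bw
    return out


# -- convolution ---------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> (N,C,Ho,Wo,kh,kw) window view (read-only)."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """2-D cross-correlation. x: (N,Cin,H,W); w: (Cout, Cin/groups, kh, kw)."""
    N, Cin, H, W = x.data.shape
    Cout, Cin_g, kh, kw = w.data.shape
    if Cin % groups or Cout % groups or Cin // groups != Cin_g:
        raise ValueError(
            f"conv2d channel/group mismatch: Cin={Cin}, Cout={Cout}, "
            f"groups={groups}, kernel expects Cin/groups={Cin_g}")
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = x.data
    Hp, Wp = xp.shape[2], xp.shape[3]
    if kh > Hp or kw > Wp:
        raise ValueError(f"kernel {kh}x{kw} larger than padded input {Hp}x{Wp}")
    cols = _im2col(xp, kh, kw, stride)                     # N,C,Ho,Wo,kh,kw
    Ho, Wo = cols.shape[2], cols.shape[3]
    # group-major layout: (N, g, Cin/g*kh*kw, Ho*Wo)
    colsg = np.ascontiguousarray(cols.transpose(0, 1, 4, 5, 2, 3)).reshape(
        N, groups, Cin_g * kh * kw, Ho * Wo)
    wg = w.data.reshape(groups, Cout // groups, Cin_g * kh * kw)
    out_data = np.matmul(wg[None], colsg).reshape(N, Cout, Ho, Wo)
    if b is not None:
        out_data += b.data.reshape(1, Cout, 1, 1)

    prev = (x, w) if b is None else (x, w, b)
    out = _node(out_data, prev)
    if out.requires_grad:
        def bw(g):
            gg = np.ascontiguousarray(g).reshape(N, groups, Cout // groups, Ho * Wo)
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                gw = np.matmul(gg, colsg.transpose(0, 1, 3, 2)).sum(axis=0)
                w._accum(gw.reshape(Cout, Cin_g, kh, kw))
            if x.requires_grad:
                gcols = np.matmul(wg.transpose(0, 2, 1)[None], gg)
                gcols = gcols.reshape(N, Cin, kh, kw, Ho, Wo)
                gx = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gx[:, :, i:i + Ho * stride:stride,
                               j:j + Wo * stride:stride] += gcols[:, :, i, j]
                if padding:
                    gx = gx[:, :, padding:-padding, padding:-padding]
                x._accum(gx)
        out._backward = bw
    return out


def maxpool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    N, C, H, W = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=-np.inf)
    win = _im2col(xp, kernel, kernel, stride)              # N,C,Ho,Wo,k,k
    Ho, Wo = win.shape[2], win.shape[3]
    flat = win.reshape(N, C, Ho, Wo, kernel * kernel)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    out = _node(out_data, (x,))
    if out.requires_grad:
        def bw(g):
            gx = np.zeros_like(xp)
            ki, kj = np.divmod(idx, kernel)
            n_i, c_i, ho_i, wo_i = np.indices(idx.shape)
            rows = ho_i * stride + ki
            cols_ = wo_i * stride + kj
            np.add.at(gx, (n_i, c_i, rows, cols_), g)
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            x._accum(gx)
        out._backward = bw
    return out


# -- 2-D Fourier transforms ------------------------------------------------------
# Both transforms are linear maps, so their backward passes are the adjoint
# transforms (the DFT matrix is symmetric; its conjugate is HW times its inverse).

def fft2_stack(x: Tensor) -> Tensor:
    """Real (N,C,H,W) -> (N,2C,H,W): real and imaginary parts of the 2-D DFT,
    stacked along channels."""
    F = np.fft.fft2(x.data, axes=(-2, -1))
    out = _node(np.concatenate([F.real, F.imag], axis=1), (x,))
    if out.requires_grad:
        C = x.data.shape[1]
        HW = x.data.shape[-2] * x.data.shape[-1]
        def bw(g):
            gc = g[:, :C] + 1j * g[:, C:]
            x._accum(HW * np.real(np.fft.ifft2(gc, axes=(-2, -1))))
        out._backward = bw
    return out


def ifft2_real(z: Tensor) -> Tensor:
    """(N,2C,H,W) stacked spectrum -> real part of the inverse 2-D DFT, (N,C,H,W)."""
    C2 = z.data.shape[1]
    C = C2 // 2
    zc = z.data[:, :C] + 1j * z.data[:, C:]
    out = _node(np.real(np.fft.ifft2(zc, axes=(-2, -1))), (z,))
    if out.requires_grad:
        def bw(g):
            gi = np.fft.ifft2(g, axes=(-2, -1))
            z._accum(np.concatenate([gi.real, -gi.imag], axis=1))
        out._backward = bw
    return out
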