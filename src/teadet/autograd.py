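"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operator set the detector and the frequency-domain
fusion module need: elementwise arithmetic, matmul, reductions, 2-D
convolution (im2col), pooling, nearest upsampling, fancy indexing with
scatter-add backward, and the real<->complex 2-D Fourier pair used by the
spectral attention block.  Tensors carry float32 data; gradients are
accumulated in float32.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "Parameter", "concat", "stack", "no_grad"]


class _NoGrad:
    """Context manager disabling graph construction."""

    _active = False

    def __enter__(self):
        self._prev = _NoGrad._active
        _NoGrad._active = True
        return self

    def __exit__(self, *exc):
        _NoGrad._active = self._prev
        return False


def no_grad():
    return _NoGrad()


def _unbroadcast(grad, shape):
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad=False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad) and not _NoGrad._active
        self._backward = None
        self._prev = ()

    # ------------------------------------------------------------------
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

    def item(self):
        return float(self.data)

    def numpy(self):
        return self.data

    def detach(self):
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # ------------------------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if not _NoGrad._active and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad):
        grad = grad.astype(np.float32, copy=False)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def build(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                build(p)
            topo.append(t)

        build(self)
        self._accum(np.asarray(grad, dtype=np.float32))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # ----------------------------- arithmetic --------------------------
    @staticmethod
    def _wrap(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data ** 2), other.data.shape)
                )

        return self._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p):
        assert isinstance(p, (int, float))

        def bw(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data ** p, (self,), bw)

    def __matmul__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), bw)

    # ----------------------------- shaping -----------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bw(g):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, idx):
        def bw(g):
            dx = np.zeros_like(self.data)
            np.add.at(dx, idx, g)
            self._accum(dx)

        return self._make(self.data[idx], (self,), bw)

    # ----------------------------- reductions --------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis, keepdims=False):
        """Max reduction; ties share the gradient equally."""
        ax = tuple(np.atleast_1d(axis))
        out = self.data.max(axis=ax, keepdims=True)
        mask = (self.data == out)
        mask = mask / mask.sum(axis=ax, keepdims=True)

        def bw(g):
            g = np.asarray(g).reshape(out.shape)
            self._accum((mask * g).astype(np.float32))

        res = out if keepdims else out.squeeze(axis=ax)
        return self._make(res, (self,), bw)

    # ----------------------------- elementwise -------------------------
    def exp(self):
        e = np.exp(self.data)

        def bw(g):
            self._accum(g * e)

        return self._make(e, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        r = np.sqrt(self.data)

        def bw(g):
            self._accum(g / (2.0 * r + 1e-12))

        return self._make(r, (self,), bw)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * s * (1.0 - s))

        return self._make(s, (self,), bw)

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * (s + self.data * s * (1.0 - s)))

        return self._make(self.data * s, (self,), bw)

    def relu(self):
        m = self.data > 0

        def bw(g):
            self._accum(g * m)

        return self._make(self.data * m, (self,), bw)

    def arctan(self):
        def bw(g):
            self._accum(g / (1.0 + self.data ** 2))

        return self._make(np.arctan(self.data), (self,), bw)

    def maximum(self, other):
        other = self._wrap(other)
        m = self.data >= other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * m, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * ~m, other.data.shape))

        return self._make(np.maximum(self.data, other.data), (self, other), bw)

    def minimum(self, other):
        other = self._wrap(other)
        m = self.data <= other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * m, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * ~m, other.data.shape))

        return self._make(np.minimum(self.data, other.data), (self, other), bw)

    def clamp(self, lo=None, hi=None):
        m = np.ones_like(self.data, dtype=bool)
        if lo is not None:
            m &= self.data >= lo
        if hi is not None:
            m &= self.data <= hi

        def bw(g):
            self._accum(g * m)

        return self._make(np.clip(self.data, lo, hi), (self,), bw)

    # ----------------------------- losses ------------------------------
    def bce_with_logits(self, target):
        """Elementwise binary cross-entropy on logits; numerically stable."""
        t = target.data if isinstance(target, Tensor) else np.asarray(target, np.float32)
        x = self.data
        loss = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))
        s = 1.0 / (1.0 + np.exp(-x))

        def bw(g):
            self._accum(g * (s - t))

        return self._make(loss, (self,), bw)

    # ----------------------------- conv & pooling -----------------------
    def conv2d(self, weight, bias=None, stride=1, padding=0):
        """2-D convolution (cross-correlation). x:(N,C,H,W), w:(Co,Ci,k,k)."""
        x, w = self.data, weight.data
        N, C, H, W = x.shape
        Co, Ci, kh, kw = w.shape
        s, p = int(stride), int(padding)
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        Ho = (xp.shape[2] - kh) // s + 1
        Wo = (xp.shape[3] - kw) // s + 1
        win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
        # (N, C, Ho, Wo, kh, kw) -> (N*Ho*Wo, C*kh*kw)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * kh * kw)
        wm = w.reshape(Co, -1)
        out = cols @ wm.T
        if bias is not None:
            out = out + bias.data
        out = out.reshape(N, Ho, Wo, Co).transpose(0, 3, 1, 2)
        parents = (self, weight) + ((bias,) if bias is not None else ())

        def bw(g):
            gm = g.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, Co)
            if weight.requires_grad:
                weight._accum((gm.T @ cols).reshape(w.shape))
            if bias is not None and bias.requires_grad:
                bias._accum(gm.sum(axis=0))
            if self.requires_grad:
                dcols = (gm @ wm).reshape(N, Ho, Wo, C, kh, kw)
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += \
                            dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                self._accum(dxp[:, :, p:p + H, p:p + W] if p else dxp)

        return self._make(out, parents, bw)

    def maxpool2d(self, k, stride=1):
        """Max pooling with 'same' padding (stride 1) as used by SPP/SPPF."""
        x = self.data
        N, C, H, W = x.shape
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
        Ho, Wo = win.shape[2], win.shape[3]
        flat = win.reshape(N, C, Ho, Wo, k * k)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

        def bw(g):
            dxp = np.zeros_like(xp)
            ii, jj = np.divmod(idx, k)
            n_, c_, y_, x_ = np.indices(idx.shape)
            np.add.at(dxp, (n_, c_, y_ * stride + ii, x_ * stride + jj), g)
            self._accum(dxp[:, :, p:p + H, p:p + W])

        return self._make(out, (self,), bw)

    def upsample2x(self):
        x = self.data
        out = x.repeat(2, axis=2).repeat(2, axis=3)
        N, C, H, W = x.shape

        def bw(g):
            self._accum(g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

        return self._make(out, (self,), bw)

    # ----------------------------- Fourier pair -------------------------
    def fft2(self):
        """Per-channel 2-D DFT of a real map. Returns (real, imag) tensors."""
        X = np.fft.fft2(self.data, axes=(-2, -1))
        M, N = self.data.shape[-2], self.data.shape[-1]
        scale = float(M * N)

        def bw_re(g):
            # adjoint of x -> Re(F x) is dre -> Re(M N ifft2(dre))
            self._accum(np.real(scale * np.fft.ifft2(g, axes=(-2, -1))).astype(np.float32))

        def bw_im(g):
            # adjoint of x -> Im(F x) is dim -> -M N Im(ifft2(dim))
            self._accum((-scale * np.imag(np.fft.ifft2(g, axes=(-2, -1)))).astype(np.float32))

        re_out = self._make(X.real.astype(np.float32), (self,), bw_re)
        im_out = self._make(X.imag.astype(np.float32), (self,), bw_im)
        return re_out, im_out

    @staticmethod
    def ifft2_real(re, im):
        """Real part of the inverse 2-D DFT of re + j*im."""
        X = re.data + 1j * im.data
        y = np.real(np.fft.ifft2(X, axes=(-2, -1))).astype(np.float32)

        def bw(g):
            G = np.fft.ifft2(g, axes=(-2, -1))
            if re.requires_grad:
                re._accum(np.real(G).astype(np.float32))
            if im.requires_grad:
                im._accum(-np.imag(G).astype(np.float32))

        return Tensor._make(y, (re, im), bw)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # parameters ignore no_grad at creation


def concat(tensors, axis=0):
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    return Tensor._make(data, tuple(tensors), bw)


def stack(tensors, axis=0):
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor._make(data, tuple(tensors), bw)
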