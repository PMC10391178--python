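"""Neural-network building blocks for the one-stage detector.

Layers follow the CSP-style one-stage detector convention: every
convolution is 'same'-padded, bias-free, followed by batch normalisation
and SiLU unless stated otherwise.  Each convolution records the spatial
size of its most recent output so that parameter/FLOP accounting
(:mod:`teadet.blocks`) can enumerate layer shapes from a single traced
forward pass.
"""
from __future__ import annotations

import math

import numpy as np

from .autograd import Parameter, Tensor, concat

__all__ = [
    "Module", "Conv2d", "BatchNorm2d", "ConvBnAct", "DSConv2d", "Focus",
    "Bottleneck", "C3", "SPP", "SPPF", "Upsample", "Detect", "autopad",
]


def autopad(k):
    # 'same' output for odd k; floor-half for even k so stride-2 halves exactly
    return (k - 1) // 2


class Module:
    """Lightweight module container with recursive parameter discovery."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    # ------------------------------------------------------------------
    def named_parameters(self, prefix=""):
        for n, p in self._params.items():
            yield (prefix + n, p)
        for n, m in self._modules.items():
            yield from m.named_parameters(prefix + n + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode=True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # ------------------------------------------------------------------
    def state_dict(self):
        return {n: p.data.copy() for n, p in self.named_parameters()}

    def load_state_dict(self, sd):
        own = dict(self.named_parameters())
        missing = set(own) - set(sd)
        extra = set(sd) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)[:4]} "
                             f"extra={sorted(extra)[:4]}")
        for n, p in own.items():
            if p.data.shape != sd[n].shape:
                raise ValueError(f"shape mismatch for {n}")
            p.data = np.asarray(sd[n], dtype=np.float32).copy()

    def __call__(self, *a, **k):
        return self.forward(*a, **k)


class Conv2d(Module):
    def __init__(self, c1, c2, k=1, s=1, p=None, bias=False, rng=None):
        super().__init__()
        self.c1, self.c2, self.k, self.s = c1, c2, k, s
        self.p = autopad(k) if p is None else p
        rng = rng or np.random.default_rng(0)
        scale = math.sqrt(2.0 / (c1 * k * k))
        self.weight = Parameter(rng.normal(0.0, scale, (c2, c1, k, k)))
        self.bias = Parameter(np.zeros(c2)) if bias else None
        self.last_hw = None  # (H_out, W_out) of most recent forward

    def forward(self, x):
        out = x.conv2d(self.weight, self.bias, stride=self.s, padding=self.p)
        self.last_hw = out.shape[-2:]
        return out


class DSConv2d(Conv2d):
    """Distribution-shift convolution: blockwise variable-quantised kernel.

    The kernel is emulated in float: each (C_in x k) kernel-row block is
    quantised to `bits` signed levels and rescaled by a learned per-block
    scale and shift, adding 2*k parameters per output channel.  A
    straight-through estimator carries gradients to the latent kernel.
    """

    def __init__(self, c1, c2, k=3, s=1, p=None, bits=4, rng=None):
        super().__init__(c1, c2, k, s, p, bias=False, rng=rng)
        self.bits = bits
        self.row_scale = Parameter(np.ones((c2, 1, k, 1)))
        self.row_shift = Parameter(np.zeros((c2, 1, k, 1)))

    def _quantised(self):
        w = self.weight
        q = 2 ** (self.bits - 1) - 1
        # per-(out-channel, kernel-row) block max-abs scale
        a = np.abs(w.data).max(axis=(1, 3), keepdims=True) / q
        a = np.maximum(a, 1e-12)
        wq = np.round(w.data / a) * a
        # straight-through: forward uses wq, gradient flows to latent w
        w_eff = w + Tensor(wq - w.data)
        return w_eff * self.row_scale + self.row_shift

    def forward(self, x):
        out = x.conv2d(self._quantised(), None, stride=self.s, padding=self.p)
        self.last_hw = out.shape[-2:]
        return out


class Linear(Module):
    def __init__(self, c_in, c_out, rng=None):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        rng = rng or np.random.default_rng(0)
        bound = math.sqrt(1.0 / c_in)
        self.weight = Parameter(rng.uniform(-bound, bound, (c_in, c_out)))
        self.bias = Parameter(np.zeros(c_out))

    def forward(self, x):
        return x @ self.weight + self.bias


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-3, momentum=0.03):
        super().__init__()
        self.c, self.eps, self.momentum = c, eps, momentum
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x):
        if self.training:
            m = x.mean(axis=(0, 2, 3), keepdims=True)
            v = ((x - m) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (m.data.ravel() - self.running_mean)
            self.running_var += self.momentum * (v.data.ravel() - self.running_var)
            xhat = (x - m) / (v + self.eps).sqrt()
        else:
            m = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            v = Tensor(self.running_var.reshape(1, -1, 1, 1))
            xhat = (x - m) / (v + self.eps).sqrt()
        g = self.gamma.reshape(1, self.c, 1, 1)
        b = self.beta.reshape(1, self.c, 1, 1)
        return xhat * g + b


class ConvBnAct(Module):
    """Conv + BN + SiLU, the detector's standard convolution unit."""

    def __init__(self, c1, c2, k=1, s=1, p=None, act=True, norm=True,
                 dsconv=False, rng=None):
        super().__init__()
        conv_cls = DSConv2d if dsconv else Conv2d
        if dsconv:
            self.conv = conv_cls(c1, c2, k, s, p, rng=rng)
        else:
            self.conv = conv_cls(c1, c2, k, s, p, bias=not norm, rng=rng)
        self.bn = BatchNorm2d(c2) if norm else None
        self.act = act

    def forward(self, x):
        x = self.conv(x)
        if self.bn is not None:
            x = self.bn(x)
        return x.silu() if self.act else x


class Focus(Module):
    """Space-to-depth slicing stem: (c,H,W) -> (4c,H/2,W/2) -> k=3 conv."""

    def __init__(self, c1, c2, k=3, s=1, rng=None):
        super().__init__()
        self.conv = ConvBnAct(4 * c1, c2, k, s, rng=rng)

    def forward(self, x):
        H, W = x.shape[-2:]
        if H % 2 or W % 2:
            raise ValueError(f"Focus stem requires even spatial size, got {H}x{W}")
        x = concat([x[..., ::2, ::2], x[..., 1::2, ::2],
                    x[..., ::2, 1::2], x[..., 1::2, 1::2]], axis=1)
        return self.conv(x)


class Bottleneck(Module):
    def __init__(self, c1, c2, shortcut=True, dsconv=False, rng=None):
        super().__init__()
        c_ = c2  # expansion 1.0 inside CSP bottlenecks
        self.cv1 = ConvBnAct(c1, c_, 1, 1, rng=rng)
        self.cv2 = ConvBnAct(c_, c2, 3, 1, dsconv=dsconv, rng=rng)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3(Module):
    """Cross-stage-partial bottleneck block (CSP1_n with shortcuts,
    CSP2/C3 without; ``dsconv=True`` gives the C3_DSConv neck variant)."""

    def __init__(self, c1, c2, n=1, shortcut=True, dsconv=False, rng=None):
        super().__init__()
        if n < 1:
            raise ValueError("repeat count must be >= 1")
        c_ = c2 // 2
        self.cv1 = ConvBnAct(c1, c_, 1, 1, rng=rng)
        self.cv2 = ConvBnAct(c1, c_, 1, 1, rng=rng)
        self.cv3 = ConvBnAct(2 * c_, c2, 1, 1, rng=rng)
        self.m = [Bottleneck(c_, c_, shortcut, dsconv=dsconv, rng=rng)
                  for _ in range(n)]
        self.n = n

    def forward(self, x):
        y = self.cv1(x)
        for b in self.m:
            y = b(y)
        return self.cv3(concat([y, self.cv2(x)], axis=1))


class SPP(Module):
    """Spatial pyramid pooling with kernel set (5, 9, 13)."""

    def __init__(self, c1, c2, k=(5, 9, 13), rng=None):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = ConvBnAct(c1, c_, 1, 1, rng=rng)
        self.cv2 = ConvBnAct(c_ * (len(k) + 1), c2, 1, 1, rng=rng)
        self.k = k

    def forward(self, x):
        x = self.cv1(x)
        return self.cv2(concat([x] + [x.maxpool2d(k) for k in self.k], axis=1))


class SPPF(Module):
    """Fast SPP: three chained k=5 poolings, parameter-identical to SPP."""

    def __init__(self, c1, c2, k=5, rng=None):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = ConvBnAct(c1, c_, 1, 1, rng=rng)
        self.cv2 = ConvBnAct(c_ * 4, c2, 1, 1, rng=rng)
        self.k = k

    def forward(self, x):
        x = self.cv1(x)
        y1 = x.maxpool2d(self.k)
        y2 = y1.maxpool2d(self.k)
        y3 = y2.maxpool2d(self.k)
        return self.cv2(concat([x, y1, y2, y3], axis=1))


class Upsample(Module):
    def forward(self, x):
        return x.upsample2x()


class Detect(Module):
    """Three 1x1 prediction convolutions, one per pyramid level.

    Each emits 3 * (num_classes + 5) channels: (tx, ty, tw, th, obj,
    class logits) per anchor.
    """

    def __init__(self, nc, anchors, ch, rng=None):
        super().__init__()
        self.nc = nc
        self.no = nc + 5
        self.na = len(anchors[0]) // 2
        self.anchors = np.asarray(anchors, dtype=np.float32).reshape(len(ch), -1, 2)
        self.strides = np.array([8, 16, 32], dtype=np.float32)[: len(ch)]
        self.m = [Conv2d(c, self.no * self.na, 1, bias=True, rng=rng) for c in ch]

    def forward(self, xs):
        return [conv(x) for conv, x in zip(self.m, xs)]

    def decode(self, raw):
        """Raw maps -> (N, n_boxes, 4+1+nc) arrays in input-pixel units
        (xc, yc, w, h, objectness, class probabilities)."""
        outs = []
        for p, stride, anchors in zip(raw, self.strides, self.anchors):
            a = p.data if isinstance(p, Tensor) else p
            N, _, H, W = a.shape
            a = a.reshape(N, self.na, self.no, H, W).transpose(0, 1, 3, 4, 2)
            s = 1.0 / (1.0 + np.exp(-a))
            gy, gx = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
            xy = (s[..., 0:2] * 2.0 - 0.5 + np.stack([gx, gy], axis=-1)) * stride
            wh = (s[..., 2:4] * 2.0) ** 2 * anchors.reshape(1, self.na, 1, 1, 2)
            obj = s[..., 4:5]
            cls = s[..., 5:] if self.nc > 1 else np.ones_like(obj)
            out = np.concatenate([xy, wh, obj, cls], axis=-1)
            outs.append(out.reshape(N, -1, out.shape[-1]))
        return np.concatenate(outs, axis=1)
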