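"""Frequency-domain cross-modal fusion attention (FFA) and the
dual-stream multimodal detector that embeds it.

The FFA block takes a pair of same-shaped feature maps — one from the
RGB stream, one from the depth/infrared (D_IR_IR) stream — and fuses
them in the frequency domain:

1. per-channel 2-D FFT of each stream;
2. channel attention: global max- and average-pooling of the two
   magnitude spectra, a shared two-layer perceptron and a sigmoid yield
   one weight per channel per stream, multiplied into the complex
   spectra (phase preserved);
3. spectral attention: the two refined magnitude spectra are
   concatenated and passed through 1x1 conv -> ReLU -> 1x1 conv ->
   sigmoid, yielding one weight per frequency bin per stream;
4. inverse FFT back to the spatial domain;
5. cross re-enhancement: each stream's purified map is passed through
   two 1x1 convolutions and added to the *other* stream's input.

All attention operates on magnitude spectra and multiplies the complex
spectra by real weights, so phase — hence spatial structure — is
invariant through steps 2-3.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, concat
from .nn import Conv2d, ConvBnAct, Detect, Linear, Module
from .model_zoo import _Neck, _build_neck, _neck_forward, \
    build_backbone, preset_config

__all__ = [
    "SpectralFeaturePair", "AttentionWeights", "spectral_transform",
    "FFABlock", "MultimodalDetector", "build_multimodal",
]

_EPS = 1e-12


@dataclass
class SpectralFeaturePair:
    """The two streams' complex spectra, stored as (real, imag) tensors."""

    rgb_re: Tensor
    rgb_im: Tensor
    dir_re: Tensor
    dir_im: Tensor
    stage: str = "raw"   # raw | channel_refined | frequency_refined

    def shapes_match(self):
        return (self.rgb_re.shape == self.rgb_im.shape ==
                self.dir_re.shape == self.dir_im.shape)


@dataclass
class AttentionWeights:
    channel_rgb: Tensor = None      # (N, C)
    channel_dir: Tensor = None
    spectral_rgb: Tensor = None     # (N, 1, M, Nf)
    spectral_dir: Tensor = None


def spectral_transform(x, direction="forward"):
    """Per-channel 2-D DFT (forward) or real-part inverse DFT.

    forward: real (N, C, M, Nf) map -> (real, imag) spectra.
    inverse: (real, imag) spectra -> real map.
    """
    if direction == "forward":
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if not np.isfinite(x.data).all():
            raise ValueError("non-finite input to spectral transform")
        return x.fft2()
    if direction == "inverse":
        re, im = x
        re = re if isinstance(re, Tensor) else Tensor(re)
        im = im if isinstance(im, Tensor) else Tensor(im)
        return Tensor.ifft2_real(re, im)
    raise ValueError(f"unknown direction {direction!r}")


def _magnitude(re, im):
    return (re * re + im * im + _EPS).sqrt()


class FFABlock(Module):
    """One cross-modal frequency-attention fusion block for C channels.

    Parameters
    ----------
    c : channel count of each stream's feature map.
    reduction : hidden-width divisor of the two attention perceptrons
        (hidden width = C // reduction).
    enhance_norm_act : whether the re-enhancement 1x1 convolutions carry
        normalisation + SiLU (the default); disable for algebraically
        exact identity configurations.
    """

    def __init__(self, c, reduction=2, enhance_norm_act=True, rng=None):
        super().__init__()
        if c < 2:
            raise ValueError("FFA needs at least 2 channels")
        rng = rng or np.random.default_rng(0)
        hidden = max(c // reduction, 2)
        self.c = c
        # channel attention: shared MLP on [max|avg of both streams] (4C)
        self.mlp1_fc1 = Linear(4 * c, hidden, rng=rng)
        self.mlp1_fc2 = Linear(hidden, 2 * c, rng=rng)
        # spectral attention: 1x1 conv stack on concatenated magnitudes
        self.mlp2_conv1 = Conv2d(2 * c, hidden, 1, bias=True, rng=rng)
        self.mlp2_conv2 = Conv2d(hidden, 2, 1, bias=True, rng=rng)
        # small-gain init on the output layers keeps both attentions near
        # 0.5 at the start of training and away from sigmoid saturation
        self.mlp1_fc2.weight.data *= 0.05
        self.mlp2_conv2.weight.data *= 0.05
        # cross re-enhancement, two 1x1 convs per stream
        na = enhance_norm_act
        self.enh_rgb = [ConvBnAct(c, c, 1, act=na, norm=na, rng=rng),
                        ConvBnAct(c, c, 1, act=na, norm=na, rng=rng)]
        self.enh_dir = [ConvBnAct(c, c, 1, act=na, norm=na, rng=rng),
                        ConvBnAct(c, c, 1, act=na, norm=na, rng=rng)]

    # ------------------------------------------------------------------
    def channel_refine(self, pair, override=None):
        """Channel attention on a raw spectral pair.

        Returns the refined pair and the two (N, C) weight vectors.
        With ``override`` set (scalar or array), the sigmoid path is
        bypassed and the given weights are used for both streams.
        """
        if pair.stage != "raw":
            raise ValueError(f"channel_refine expects a raw pair, got {pair.stage!r}")
        if not pair.shapes_match():
            raise ValueError("stream shape mismatch")
        if override is None:
            # magnitudes scaled by 1/sqrt(M*N) (orthonormal DFT scale) so
            # pooled statistics are O(1) regardless of map size
            s = 1.0 / float(np.sqrt(np.prod(pair.rgb_re.shape[2:])))
            m_rgb = _magnitude(pair.rgb_re, pair.rgb_im) * s
            m_dir = _magnitude(pair.dir_re, pair.dir_im) * s
            vec = concat([m_rgb.max(axis=(2, 3)), m_rgb.mean(axis=(2, 3)),
                          m_dir.max(axis=(2, 3)), m_dir.mean(axis=(2, 3))],
                         axis=1)                                  # (N, 4C)
            w = self.mlp1_fc2(self.mlp1_fc1(vec).relu()).sigmoid()  # (N, 2C)
            w_rgb, w_dir = w[:, : self.c], w[:, self.c:]
        else:
            n = pair.rgb_re.shape[0]
            w_rgb = w_dir = Tensor(np.broadcast_to(
                np.asarray(override, dtype=np.float32), (n, self.c)).copy())
        wr = w_rgb.reshape(w_rgb.shape[0], self.c, 1, 1)
        wd = w_dir.reshape(w_dir.shape[0], self.c, 1, 1)
        out = SpectralFeaturePair(
            pair.rgb_re * wr, pair.rgb_im * wr,
            pair.dir_re * wd, pair.dir_im * wd, stage="channel_refined")
        return out, (w_rgb, w_dir)

    def frequency_refine(self, pair, override=None):
        """Per-frequency attention on a channel-refined spectral pair.

        Returns the refined pair and the two (N, 1, M, Nf) weight maps.
        """
        if pair.stage != "channel_refined":
            raise ValueError(
                f"frequency_refine expects a channel_refined pair, got {pair.stage!r}")
        if not pair.shapes_match():
            raise ValueError("stream shape mismatch")
        if override is None:
            s = 1.0 / float(np.sqrt(np.prod(pair.rgb_re.shape[2:])))
            m = concat([_magnitude(pair.rgb_re, pair.rgb_im) * s,
                        _magnitude(pair.dir_re, pair.dir_im) * s], axis=1)
            w = self.mlp2_conv2(self.mlp2_conv1(m).relu()).sigmoid()  # (N,2,M,Nf)
            w_rgb, w_dir = w[:, 0:1], w[:, 1:2]
        else:
            shape = (pair.rgb_re.shape[0], 1) + pair.rgb_re.shape[2:]
            w_rgb = w_dir = Tensor(np.broadcast_to(
                np.asarray(override, dtype=np.float32), shape).copy())
        out = SpectralFeaturePair(
            pair.rgb_re * w_rgb, pair.rgb_im * w_rgb,
            pair.dir_re * w_dir, pair.dir_im * w_dir,
            stage="frequency_refined")
        return out, (w_rgb, w_dir)

    # ------------------------------------------------------------------
    def forward(self, f_rgb, f_dir, channel_override=None,
                spectral_override=None):
        """Fuse a feature-map pair; returns the updated (f_rgb, f_dir)."""
        if not isinstance(f_rgb, Tensor):
            f_rgb = Tensor(f_rgb)
        if not isinstance(f_dir, Tensor):
            f_dir = Tensor(f_dir)
        if f_rgb.shape != f_dir.shape:
            raise ValueError(f"stream shapes differ: {f_rgb.shape} vs {f_dir.shape}")
        if f_rgb.ndim != 4 or f_rgb.shape[1] != self.c or min(f_rgb.shape[2:]) < 2:
            raise ValueError(f"expected (N, {self.c}, M>=2, N>=2), got {f_rgb.shape}")
        rr, ri = spectral_transform(f_rgb)
        dr, di = spectral_transform(f_dir)
        pair = SpectralFeaturePair(rr, ri, dr, di, stage="raw")
        pair, (wc_r, wc_d) = self.channel_refine(pair, override=channel_override)
        pair, (wf_r, wf_d) = self.frequency_refine(pair, override=spectral_override)
        pure_rgb = spectral_transform((pair.rgb_re, pair.rgb_im), "inverse")
        pure_dir = spectral_transform((pair.dir_re, pair.dir_im), "inverse")
        # cross wiring: the purified D_IR map re-enhances the RGB stream
        out_rgb = self.enh_rgb[1](self.enh_rgb[0](pure_dir)) + f_rgb
        out_dir = self.enh_dir[1](self.enh_dir[0](pure_rgb)) + f_dir
        self.last_weights = AttentionWeights(wc_r, wc_d, wf_r, wf_d)
        return out_rgb, out_dir


class MultimodalDetector(Module):
    """Dual-stream detector: two unshared backbones over the RGB and
    D_IR_IR composites, fused at the three pyramid-producing stages.

    With ``use_ffa=True`` each fusion point is an FFA block whose
    outputs are re-injected into both streams before summation; with
    ``use_ffa=False`` the pyramid features are the plain elementwise sum
    of the two streams (the ablation mode)."""

    STAGE_SLICES = ((0, 5), (5, 7), (7, 10))  # backbone index ranges per stage

    def __init__(self, config=None, use_ffa=True, reduction=2, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        cfg = config or preset_config("improved")
        if cfg.in_channels != 3:
            raise ValueError("each stream of the multimodal model takes 3 channels")
        self.config = cfg
        self.use_ffa = use_ffa
        self.backbone_rgb = build_backbone(cfg, rng)
        self.backbone_dir = build_backbone(cfg, rng)
        w = cfg.width
        self.stage_channels = (w(256), w(512), w(1024))
        if use_ffa:
            self.ffa = [FFABlock(c, reduction=reduction, rng=rng)
                        for c in self.stage_channels]
        self.neck = _Neck(_build_neck(cfg, rng))
        self.detect = Detect(cfg.num_classes, cfg.anchors,
                             list(self.stage_channels), rng=rng)

    def multimodal_forward(self, rgb, d_ir):
        """Fused pyramid features (BP3, BP4, BP5) for an aligned pair."""
        if not isinstance(rgb, Tensor):
            rgb = Tensor(rgb)
        if not isinstance(d_ir, Tensor):
            d_ir = Tensor(d_ir)
        if rgb.shape != d_ir.shape:
            raise ValueError("misaligned inputs: stream shapes differ")
        r, d = rgb, d_ir
        pyramid = []
        for k, (a, b) in enumerate(self.STAGE_SLICES):
            for i in range(a, b):
                r = self.backbone_rgb[i](r)
                d = self.backbone_dir[i](d)
            if self.use_ffa:
                r, d = self.ffa[k](r, d)
            pyramid.append(r + d)
        return tuple(pyramid)

    def forward(self, rgb, d_ir):
        bp3, bp4, bp5 = self.multimodal_forward(rgb, d_ir)
        feats = _neck_forward(self.neck, {"p3": bp3, "p4": bp4, "p5": bp5})
        return self.detect(feats)


def build_multimodal(use_ffa=True, config=None, reduction=2, rng=None):
    return MultimodalDetector(config=config, use_ffa=use_ffa,
                              reduction=reduction, rng=rng)
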