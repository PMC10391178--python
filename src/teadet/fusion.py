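"""Data-layer fusion operators producing the three multimodal input
variants: weighted pixel summation, RGBA channel stacking, and the
depth/infrared composite (D_IR_IR) for the dual-stream model.

All operators work in normalised [0, 1] space (see
:func:`normalize_modality`); re-quantisation to 8-bit happens only when
images are written to disk.  Every operator is pixelwise, so fusion
commutes with spatial cropping.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FusionWeights", "normalize_modality", "fuse_weighted",
           "fuse_rgba", "make_d_ir_ir"]


@dataclass(frozen=True)
class FusionWeights:
    """Pixel-summation weights; the study's selected coefficients are
    (0.6, 0.2, 0.2) for method 1 and (0.5, 0.5) for method 2's alpha
    channel."""

    w_rgb: float = 0.6
    w_ir: float = 0.2
    w_depth: float = 0.2
    w_ir2: float = 0.5
    w_depth2: float = 0.5

    def __post_init__(self):
        if min(self.w_rgb, self.w_ir, self.w_depth, self.w_ir2, self.w_depth2) < 0:
            raise ValueError("fusion weights must be nonnegative")
        if abs(self.w_rgb + self.w_ir + self.w_depth - 1.0) > 1e-6:
            raise ValueError("method-1 weights must sum to 1")
        if abs(self.w_ir2 + self.w_depth2 - 1.0) > 1e-6:
            raise ValueError("method-2 weights must sum to 1")


def normalize_modality(image, source_bit_depth):
    """Linear map of integer imagery to [0, 1] by 2^bits - 1."""
    if source_bit_depth not in (8, 16):
        raise ValueError(f"unsupported bit depth {source_bit_depth}")
    return np.asarray(image, dtype=np.float64) / (2 ** source_bit_depth - 1)


def _check_aligned(rgb, ir, depth):
    hw = rgb.shape[:2]
    for name, im in (("ir", ir), ("depth", depth)):
        if im.shape[:2] != hw:
            raise ValueError(f"{name} shape {im.shape[:2]} misaligned with rgb {hw}")
        if im.ndim != 2:
            raise ValueError(f"{name} must be single-channel")
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("rgb must be HxWx3")


def fuse_weighted(rgb, ir, depth, weights=FusionWeights()):
    """Method 1: weighted pixel-level summation into one 3-channel image.

    IR and depth broadcast across the three colour channels."""
    _check_aligned(rgb, ir, depth)
    return (weights.w_rgb * rgb
            + weights.w_ir * ir[..., None]
            + weights.w_depth * depth[..., None])


def fuse_rgba(rgb, ir, depth, weights=FusionWeights()):
    """Method 2: alpha channel A = w_ir2*ir + w_depth2*depth stacked
    behind the untouched RGB planes -> HxWx4."""
    _check_aligned(rgb, ir, depth)
    a = weights.w_ir2 * ir + weights.w_depth2 * depth
    return np.concatenate([rgb, a[..., None]], axis=2)


def make_d_ir_ir(depth, ir):
    """Method 3: stack (depth, ir, ir) into the D_IR_IR composite fed to
    the second stream of the dual-stream model."""
    if depth.shape != ir.shape or depth.ndim != 2:
        raise ValueError("depth and ir must be aligned single-channel images")
    return np.stack([depth, ir, ir], axis=2)
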