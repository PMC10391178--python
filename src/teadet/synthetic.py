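"""Seeded generator of aligned RGB/IR/depth scenes with dense tiny
elongated objects and ground-truth boxes.

The generator emulates the statistical structure of the field corpus the
detector targets: 512x360 frames containing 200-400 bud-like targets
whose relative scale is mostly below 5%, coloured close to the
background, imaged by a short-range depth sensor (0.5-1.0 m) whose depth
and infrared channels carry voids and speckle.  Objects are rendered as
anti-aliased two-lobe strokes (bud + leaf) with varying pose; the same
alpha mask drives all three modalities, so the triplet is pixel-aligned
by construction.  Generation is bit-reproducible for a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .data_io import (Box, BoxAnnotationSet, ModalityTriplet, save_triplet,
                      write_labels, write_manifest)

__all__ = ["SceneConfig", "generate_scene", "generate_corpus"]

_DEPTH_FULL_SCALE_M = 2.0   # metres mapped to the top of the stored range


@dataclass(frozen=True)
class SceneConfig:
    """Study-condition defaults; every field is a config knob."""

    width: int = 512
    height: int = 360
    n_objects: tuple = (200, 400)        # uniform range per image
    mean_rel_scale: float = 0.035        # lognormal median of sqrt(area frac.)
    rel_scale_sigma: float = 0.30        # lognormal sigma (log-space)
    aspect_range: tuple = (0.45, 2.2)    # w/h of the object box
    color_contrast: float = 0.25         # object-background offset, [0, 1]
    depth_range_m: tuple = (0.5, 1.0)    # background plane distance
    object_depth_offset_m: float = 0.06  # objects sit this much nearer
    depth_void_rate: float = 0.05        # fraction of zeroed depth pixels
    ir_contrast: float = 0.4             # object reflectance gain in IR
    ir_speckle: float = 0.15             # multiplicative speckle sigma
    depth_bits: int = 8                  # 8 per the capture format; 16 optional
    max_tries_per_object: int = 20

    def __post_init__(self):
        if self.width < 16 or self.height < 16:
            raise ValueError("scene too small")
        lo, hi = self.n_objects
        if not (1 <= lo <= hi):
            raise ValueError("n_objects range invalid")
        if not 0 <= self.depth_void_rate <= 1:
            raise ValueError("void rate must be a probability")
        if self.depth_bits not in (8, 16):
            raise ValueError("depth_bits must be 8 or 16")


def _smooth_field(rng, h, w, coarse=8, lo=0.0, hi=1.0):
    """Low-frequency random field in [lo, hi]."""
    g = rng.random((coarse, coarse))
    z = ndimage.zoom(g, (h / coarse, w / coarse), order=3, mode="nearest")
    z = z[:h, :w]
    z = (z - z.min()) / max(z.max() - z.min(), 1e-9)
    return lo + (hi - lo) * z


def _stroke_mask(rng, bw, bh):
    """Anti-aliased two-lobe stroke (bud + leaf) on a bh x bw grid."""
    yy, xx = np.mgrid[0:bh, 0:bw]
    pts = np.stack([xx, yy], axis=-1).astype(np.float64)
    cx, cy = (bw - 1) / 2.0, (bh - 1) / 2.0
    theta = rng.uniform(0, np.pi)
    co, si = np.cos(theta), np.sin(theta)
    half = 0.5 * np.hypot(bw, bh) * 0.45
    alpha = np.zeros((bh, bw))
    t = np.linspace(-1.0, 1.0, 32)
    for lobe, (scale, bend, off) in enumerate(
            [(1.0, rng.uniform(-0.35, 0.35), 0.0),
             (0.55, rng.uniform(-0.6, 0.6), rng.uniform(-0.25, 0.25))]):
        # quadratic stroke through the centre in direction theta
        along = scale * half * t
        across = bend * half * (t ** 2 - 0.3) + off * half
        px = cx + along * co - across * si
        py = cy + along * si + across * co
        r = (0.16 + 0.22 * (1 - np.abs(t))) * min(bw, bh) / 2.0  # tapered radius
        d2 = ((pts[..., 0][..., None] - px) ** 2
              + (pts[..., 1][..., None] - py) ** 2)
        cover = np.clip(1.5 - np.sqrt(d2) / np.maximum(r, 0.6), 0, 1).max(axis=-1)
        alpha = np.maximum(alpha, np.clip(cover, 0, 1))
    return np.clip(alpha, 0.0, 1.0)


def generate_scene(config=None, seed=0):
    """Render one aligned triplet plus ground-truth boxes.

    Returns ``(ModalityTriplet, BoxAnnotationSet)``; boxes are tight to
    the rendered alpha support and always pass the >2x2 px annotation
    filter.
    """
    cfg = config or SceneConfig()
    rng = np.random.default_rng(seed)
    H, W = cfg.height, cfg.width

    # --- background: low-frequency green texture -----------------------
    base = _smooth_field(rng, H, W, lo=0.25, hi=0.55)
    rgb = np.stack([base * 0.75, base, base * 0.55], axis=-1)
    rgb += rng.normal(0, 0.015, rgb.shape)

    depth_m = _smooth_field(rng, H, W, lo=cfg.depth_range_m[0],
                            hi=cfg.depth_range_m[1])
    refl = _smooth_field(rng, H, W, coarse=12, lo=0.25, hi=0.6)

    alpha_all = np.zeros((H, W))
    boxes = []
    n_target = int(rng.integers(cfg.n_objects[0], cfg.n_objects[1] + 1))
    diag = np.sqrt(W * H)
    placed = 0
    failures = 0
    while placed < n_target:
        if failures > cfg.max_tries_per_object * n_target:
            raise RuntimeError(
                f"infeasible placement: {placed}/{n_target} objects after "
                f"{failures} failed tries")
        r = np.exp(rng.normal(np.log(cfg.mean_rel_scale), cfg.rel_scale_sigma))
        r = float(np.clip(r, 4.5 / diag, 0.25))
        aspect = rng.uniform(*cfg.aspect_range)
        bw = int(round(r * diag * np.sqrt(aspect)))
        bh = int(round(r * diag / np.sqrt(aspect)))
        bw, bh = max(bw, 4), max(bh, 4)
        if bw >= W // 2 or bh >= H // 2:
            failures += 1
            continue
        x0 = int(rng.integers(0, W - bw))
        y0 = int(rng.integers(0, H - bh))
        mask = _stroke_mask(rng, bw, bh)
        ys, xs = np.where(mask > 0.3)
        if len(ys) == 0:
            failures += 1
            continue
        # stretch the stroke so its tight support fills the drawn box:
        # the drawn (bw, bh) then IS the realised object size
        crop = mask[ys.min():ys.max() + 1, xs.min():xs.max() + 1]
        mask = np.clip(ndimage.zoom(
            crop, (bh / crop.shape[0], bw / crop.shape[1]), order=1), 0, 1)
        mask = mask[:bh, :bw]
        if mask.shape != (bh, bw):
            mask = np.pad(mask, ((0, bh - mask.shape[0]), (0, bw - mask.shape[1])))
        ys, xs = np.where(mask > 0.3)
        if len(ys) == 0:
            failures += 1
            continue
        ty0, ty1 = ys.min(), ys.max() + 1
        tx0, tx1 = xs.min(), xs.max() + 1
        if (ty1 - ty0) <= 2 or (tx1 - tx0) <= 2:  # must survive the 2x2 filter
            failures += 1
            continue
        sl = (slice(y0, y0 + bh), slice(x0, x0 + bw))
        alpha_all[sl] = np.maximum(alpha_all[sl], mask)

        # RGB: hue offset toward yellow-green, proportional to contrast
        dv = cfg.color_contrast * np.array([0.30, 0.35, 0.05])
        rgb[sl] += mask[..., None] * dv
        # depth: objects sit nearer the sensor
        depth_m[sl] -= mask * cfg.object_depth_offset_m
        # IR: higher reflectance on fresh growth
        refl[sl] += mask * cfg.ir_contrast

        xc = (x0 + (tx0 + tx1) / 2.0) / W
        yc = (y0 + (ty0 + ty1) / 2.0) / H
        boxes.append(Box(0, xc, yc, (tx1 - tx0) / W, (ty1 - ty0) / H))
        placed += 1

    # --- quantise the three modalities ---------------------------------
    rgb8 = (np.clip(rgb, 0, 1) * 255).round().astype(np.uint8)

    void = _smooth_field(rng, H, W, coarse=24) < cfg.depth_void_rate
    depth_frac = np.clip(depth_m / _DEPTH_FULL_SCALE_M, 0, 1)
    full = 2 ** cfg.depth_bits - 1
    depth_q = (depth_frac * full).round()
    depth_q[void] = 0
    depth_q = depth_q.astype(np.uint8 if cfg.depth_bits == 8 else np.uint16)

    speckle = np.exp(rng.normal(0, cfg.ir_speckle, (H, W)))
    ir = np.clip(refl * speckle, 0, 1)
    ir16 = (ir * 65535).round().astype(np.uint16)

    triplet = ModalityTriplet(rgb8, ir16, depth_q.astype(np.uint8)
                              if cfg.depth_bits == 8 else depth_q,
                              frame_id=f"scene_{seed:06d}")
    ann = BoxAnnotationSet(triplet.frame_id, W, H, boxes)
    return triplet, ann


def generate_corpus(config, n_images, seed, out_dir, mean_scales=None):
    """Write a synthetic corpus (triplets + labels in both formats +
    manifest) to ``out_dir``.

    ``mean_scales``: optional sequence of mean relative scales; one
    sub-corpus per entry is written to ``out_dir/subset_<k>``, emulating
    two acquisition dates with different object growth stages.  Returns
    the manifest path(s).
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    cfg = config or SceneConfig()
    if mean_scales is not None:
        return [generate_corpus(replace(cfg, mean_rel_scale=s), n_images,
                                seed + 1000 * k, Path(out_dir) / f"subset_{k}")
                for k, s in enumerate(mean_scales)]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(seed).generate_state(n_images) % (2 ** 31)
    rows = []
    for i, s in enumerate(seeds):
        triplet, ann = generate_scene(cfg, int(s))
        triplet.frame_id = f"frame_{i:04d}"
        ann.image_id = triplet.frame_id
        paths = save_triplet(triplet, out)
        write_labels(ann, out / f"{triplet.frame_id}.txt", "yolo_txt")
        write_labels(ann, out / f"{triplet.frame_id}.json", "coco_json")
        rows.append({"frame_id": triplet.frame_id, "rgb": paths["rgb"].name,
                     "ir": paths["ir"].name, "depth": paths["depth"].name,
                     "labels": f"{triplet.frame_id}.txt"})
    manifest = out / "manifest.tsv"
    write_manifest(rows, manifest)
    return manifest
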