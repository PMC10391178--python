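"""Object-based scale matching.

Aligns one detection dataset's object-scale distribution to another's:
compute each dataset's mean relative scale (s1, s2), derive the global
scale factor a = s_target / s_source, then cut every over-threshold
object out of its image, resample it by a, and paste it back centred at
its original position.  Shrinking vacates a ring of pixels around the
object; it is filled by nearest-pixel interpolation from the surrounding
pre-edit context so no pixel is left unassigned.  Enlarged objects
overwrite underlying pixels and are clipped at image bounds.

Relative scale of a box is sqrt((w*h)/(W*H)) — the geometric-mean side
fraction, symmetric in width and height.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .data_io import Box, BoxAnnotationSet

__all__ = ["ScaleStats", "relative_scale", "dataset_scale_stats",
           "rescale_object", "match_dataset"]


@dataclass
class ScaleStats:
    """Per-dataset relative-scale summary."""

    s: float                 # mean relative scale
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    n_objects: int

    def scale_factor_to(self, other):
        """Factor a that maps this dataset's mean scale onto ``other``'s
        (a_21 = s1/s2 when self is dataset 2 and other dataset 1)."""
        return other.s / self.s


def relative_scale(box, image_hw=None):
    """sqrt(area fraction) of a box.

    Accepts a normalised :class:`Box` (image size not needed) or a
    pixel (w, h) pair together with ``image_hw``.
    """
    if isinstance(box, Box):
        if box.w <= 0 or box.h <= 0:
            raise ValueError("degenerate box")
        return float(np.sqrt(box.w * box.h))
    w, h = box
    if w <= 0 or h <= 0:
        raise ValueError("degenerate box")
    if image_hw is None:
        raise ValueError("pixel boxes need image_hw")
    H, W = image_hw
    return float(np.sqrt((w * h) / (W * H)))


def dataset_scale_stats(annotations, bin_width=0.005):
    """Mean relative scale and histogram over one or many annotation sets."""
    if isinstance(annotations, BoxAnnotationSet):
        annotations = [annotations]
    scales = np.array([relative_scale(b) for ann in annotations
                       for b in ann.boxes])
    if scales.size == 0:
        raise ValueError("empty annotation collection")
    edges = np.arange(0.0, scales.max() + 2 * bin_width, bin_width)
    counts, edges = np.histogram(scales, bins=edges)
    return ScaleStats(float(scales.mean()), counts, edges, int(scales.size))


# ----------------------------------------------------------------------
def _pixel_box(box, W, H):
    x, y, w, h = box.to_pixels(W, H)
    x0, y0 = int(round(x)), int(round(y))
    x1, y1 = int(round(x + w)), int(round(y + h))
    return max(x0, 0), max(y0, 0), min(x1, W), min(y1, H)


def rescale_object(image, box, factor):
    """Cut the object under ``box`` out of ``image``, resample it by
    ``factor`` and re-paste it centred at the original box centre.

    Returns ``(image', box')``.  ``factor == 1`` is the bit-exact
    identity.  For ``factor < 1`` the vacated ring is filled with the
    nearest surrounding pre-edit pixel; for ``factor > 1`` the enlarged
    patch overwrites and is clipped at image bounds.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    H, W = image.shape[:2]
    if factor == 1.0:
        return image.copy(), box
    x0, y0, x1, y1 = _pixel_box(box, W, H)
    if x1 - x0 < 1 or y1 - y0 < 1:
        raise ValueError("box is outside the image")
    patch = image[y0:y1, x0:x1].copy()
    nh = int(round((y1 - y0) * factor))
    nw = int(round((x1 - x0) * factor))
    if nh < 1 or nw < 1:
        warnings.warn("scale factor shrinks the object below 1 px; clamping")
        nh, nw = max(nh, 1), max(nw, 1)
    out_shape = (nh, nw) + patch.shape[2:]
    resized = resize(patch.astype(np.float64), out_shape, order=1,
                     anti_aliasing=factor < 1, preserve_range=True)
    resized = resized.round().astype(image.dtype) if np.issubdtype(
        image.dtype, np.integer) else resized.astype(image.dtype)

    out = image.copy()
    if factor < 1:
        # fill the vacated box from the nearest outside-context pixel
        hole = np.zeros((H, W), dtype=bool)
        hole[y0:y1, x0:x1] = True
        iy, ix = ndimage.distance_transform_edt(
            hole, return_distances=False, return_indices=True)
        out[y0:y1, x0:x1] = image[iy, ix][y0:y1, x0:x1]

    # paste centred at the original centre, clipped at bounds
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    px0, py0 = int(round(cx - nw / 2.0)), int(round(cy - nh / 2.0))
    sx0, sy0 = max(-px0, 0), max(-py0, 0)
    dx0, dy0 = max(px0, 0), max(py0, 0)
    dx1, dy1 = min(px0 + nw, W), min(py0 + nh, H)
    out[dy0:dy1, dx0:dx1] = resized[sy0:sy0 + dy1 - dy0, sx0:sx0 + dx1 - dx0]

    new_box = Box(box.cls,
                  xc=(dx0 + dx1) / 2.0 / W, yc=(dy0 + dy1) / 2.0 / H,
                  w=(dx1 - dx0) / W, h=(dy1 - dy0) / H)
    return out, new_box


def match_dataset(items, target_s, judge_threshold=None):
    """Scale-match a dataset to a reference mean relative scale.

    ``items``: sequence of ``(image, BoxAnnotationSet)`` pairs.  Objects
    whose relative scale exceeds ``judge_threshold`` (default: the
    target mean itself) are rescaled by the single global factor
    a = target_s / s_source.  Object count and class labels are
    conserved; centres are preserved up to boundary clipping.
    Overlapping boxes are processed in decreasing-area order so the
    smallest objects are pasted last and stay intact.

    Returns ``(items', factor)``.
    """
    items = list(items)
    if not items:
        raise ValueError("empty dataset")
    stats = dataset_scale_stats([ann for _, ann in items])
    factor = float(target_s / stats.s)
    thr = target_s if judge_threshold is None else judge_threshold
    out = []
    for image, ann in items:
        img = image.copy()
        order = sorted(range(len(ann.boxes)),
                       key=lambda i: ann.boxes[i].w * ann.boxes[i].h,
                       reverse=True)
        new_boxes = list(ann.boxes)
        for i in order:
            b = ann.boxes[i]
            if relative_scale(b) > thr and factor != 1.0:
                img, nb = rescale_object(img, b, factor)
                new_boxes[i] = nb
        out.append((img, replace(ann, boxes=new_boxes)))
    return out, factor
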