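"""Aligned-triplet and annotation I/O.

A capture frame is a :class:`ModalityTriplet`: an 8-bit 3-channel RGB
image, a 16-bit single-channel infrared image and an 8-bit single-channel
depth image, pixel-aligned, with one shared :class:`BoxAnnotationSet`
(label sharing: the RGB annotations apply verbatim to IR and depth).

Conventions: pixel coordinates are 0-based with half-open boxes
[x, x+w); normalised coordinates divide by image width/height.  Labels
round-trip between COCO-style JSON (absolute top-left x, y, w, h) and
YOLO-style text (normalised centre x, y, w, h) without loss beyond
float printing precision.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "Box", "BoxAnnotationSet", "ModalityTriplet", "load_triplet",
    "save_triplet", "crop_fov", "filter_annotations", "read_labels",
    "write_labels", "write_manifest", "read_manifest",
]


@dataclass(frozen=True)
class Box:
    """One object: class id + normalised centre-form coordinates."""

    cls: int
    xc: float
    yc: float
    w: float
    h: float

    def to_pixels(self, width, height):
        """(x_left, y_top, w, h) in pixels."""
        return ((self.xc - self.w / 2) * width, (self.yc - self.h / 2) * height,
                self.w * width, self.h * height)


@dataclass
class BoxAnnotationSet:
    image_id: str
    width: int
    height: int
    boxes: list = field(default_factory=list)

    def __post_init__(self):
        for i, b in enumerate(self.boxes):
            if not (0 <= b.xc <= 1 and 0 <= b.yc <= 1 and 0 < b.w <= 1 and 0 < b.h <= 1):
                raise ValueError(f"box {i} has coordinates outside [0, 1]")

    def __len__(self):
        return len(self.boxes)


@dataclass
class ModalityTriplet:
    rgb: np.ndarray      # (H, W, 3) uint8
    ir: np.ndarray       # (H, W) uint16
    depth: np.ndarray    # (H, W) uint8
    frame_id: str = ""
    aligned: bool = True

    def __post_init__(self):
        hw = self.rgb.shape[:2]
        if self.ir.shape != hw:
            raise ValueError(f"ir shape {self.ir.shape} misaligned with rgb {hw}")
        if self.depth.shape != hw:
            raise ValueError(f"depth shape {self.depth.shape} misaligned with rgb {hw}")

    @property
    def shape(self):
        return self.rgb.shape[:2]


_EXPECTED = {"rgb": (np.uint8, 3), "ir": (np.uint16, 2), "depth": (np.uint8, 2)}


def load_triplet(rgb_path, ir_path, depth_path, frame_id=None, strict=True):
    """Decode the three modality files, enforcing bit depths and shapes.

    With ``strict=False`` an 8-bit file supplied for the 16-bit IR slot
    is promoted losslessly (value * 257); with ``strict=True`` it is an
    error naming the modality.
    """
    imgs = {}
    for name, path in (("rgb", rgb_path), ("ir", ir_path), ("depth", depth_path)):
        arr = iio.imread(path)
        want_dtype, want_ndim = _EXPECTED[name]
        if arr.ndim != want_ndim:
            raise ValueError(f"{name}: expected {want_ndim}-d image, got shape {arr.shape}")
        if arr.dtype != want_dtype:
            if name == "ir" and arr.dtype == np.uint8 and not strict:
                arr = arr.astype(np.uint16) * 257  # lossless 8->16 bit
            else:
                raise ValueError(f"{name}: expected {np.dtype(want_dtype).name}, "
                                 f"got {arr.dtype.name}")
        imgs[name] = arr
    return ModalityTriplet(imgs["rgb"], imgs["ir"], imgs["depth"],
                           frame_id=frame_id or Path(rgb_path).stem)


def save_triplet(triplet, directory, stem=None):
    """Write the triplet as PNGs (16-bit PNG for IR); returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or triplet.frame_id or "frame"
    paths = {}
    for name, arr in (("rgb", triplet.rgb), ("ir", triplet.ir),
                      ("depth", triplet.depth)):
        p = directory / f"{stem}_{name}.png"
        iio.imwrite(p, arr)
        paths[name] = p
    return paths


# ----------------------------------------------------------------------
def crop_fov(triplet, annotations, target_h):
    """Remove rows outside the shared field of view.

    (H - target_h) rows are split evenly top/bottom (odd remainder to
    the bottom); annotations are shifted and renormalised, boxes fully
    outside are dropped, straddling boxes are clipped (dropped if the
    clipped area falls below 1 px^2).
    """
    H, W = triplet.shape
    if target_h > H:
        raise ValueError(f"target_h {target_h} exceeds image height {H}")
    cut = H - target_h
    if cut == 0:
        return triplet, annotations
    top = cut // 2
    out = ModalityTriplet(
        triplet.rgb[top:top + target_h],
        triplet.ir[top:top + target_h],
        triplet.depth[top:top + target_h],
        frame_id=triplet.frame_id, aligned=triplet.aligned)
    boxes = []
    for b in annotations.boxes:
        x, y, w, h = b.to_pixels(W, H)
        y -= top
        y0, y1 = max(y, 0.0), min(y + h, float(target_h))
        if y1 - y0 < 1e-9 or w * (y1 - y0) < 1.0:
            continue
        boxes.append(Box(b.cls,
                         xc=(x + w / 2) / W,
                         yc=(y0 + y1) / 2 / target_h,
                         w=w / W,
                         h=(y1 - y0) / target_h))
    return out, BoxAnnotationSet(annotations.image_id, W, target_h, boxes)


def filter_annotations(annotations, min_side_px=2):
    """Keep objects whose pixel width AND height strictly exceed
    ``min_side_px`` (the annotation rule: absolute size larger than
    2x2 px)."""
    if min_side_px < 1:
        raise ValueError("min_side_px must be >= 1")
    W, H = annotations.width, annotations.height
    kept = [b for b in annotations.boxes
            if b.w * W > min_side_px and b.h * H > min_side_px]
    return replace(annotations, boxes=kept)


# ----------------------------------------------------------------------
def _boxes_to_coco(ann):
    return {
        "images": [{"id": 0, "file_name": ann.image_id,
                    "width": ann.width, "height": ann.height}],
        "categories": [{"id": c, "name": str(c)}
                       for c in sorted({b.cls for b in ann.boxes}) or [0]],
        "annotations": [
            {"id": i, "image_id": 0, "category_id": b.cls,
             "bbox": list(b.to_pixels(ann.width, ann.height)),
             "area": b.w * ann.width * b.h * ann.height, "iscrowd": 0}
            for i, b in enumerate(ann.boxes)],
    }


def write_labels(annotations, path, fmt):
    path = Path(path)
    if fmt == "coco_json":
        path.write_text(json.dumps(_boxes_to_coco(annotations), indent=1))
    elif fmt == "yolo_txt":
        lines = [f"{b.cls} {b.xc:.6f} {b.yc:.6f} {b.w:.6f} {b.h:.6f}"
                 for b in annotations.boxes]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    else:
        raise ValueError(f"unknown label format {fmt!r}")


def read_labels(path, fmt, image_id=None, width=None, height=None):
    """Read a label file; COCO carries image size itself, YOLO needs it."""
    path = Path(path)
    if fmt == "coco_json":
        doc = json.loads(path.read_text())
        img = doc["images"][0]
        W, H = img["width"], img["height"]
        boxes = []
        for i, a in enumerate(doc["annotations"]):
            x, y, w, h = a["bbox"]
            if w <= 0 or h <= 0:
                raise ValueError(f"record {i}: non-positive box size {w}x{h}")
            boxes.append(Box(a["category_id"], (x + w / 2) / W, (y + h / 2) / H,
                             w / W, h / H))
        return BoxAnnotationSet(image_id or img["file_name"], W, H, boxes)
    if fmt == "yolo_txt":
        if width is None or height is None:
            raise ValueError("yolo_txt needs explicit image width/height")
        boxes = []
        for ln, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(f"line {ln}: expected 5 fields, got {len(parts)}")
            c, xc, yc, w, h = int(parts[0]), *map(float, parts[1:])
            if w <= 0 or h <= 0:
                raise ValueError(f"line {ln}: non-positive box size")
            boxes.append(Box(c, xc, yc, w, h))
        return BoxAnnotationSet(image_id or path.stem, width, height, boxes)
    raise ValueError(f"unknown label format {fmt!r}")


# ----------------------------------------------------------------------
def write_manifest(rows, path):
    """Plain-text dataset manifest: frame id -> image paths + label path."""
    lines = ["\t".join(["frame_id", "rgb", "ir", "depth", "labels"])]
    for r in rows:
        lines.append("\t".join(str(r[k]) for k in
                               ("frame_id", "rgb", "ir", "depth", "labels")))
    Path(path).write_text("\n".join(lines) + "\n")


def read_manifest(path):
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    return [dict(zip(header, ln.split("\t"))) for ln in lines[1:] if ln.strip()]
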