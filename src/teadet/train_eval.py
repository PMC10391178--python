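"""Loss, detection metrics, training loop and the scale-matched
transfer-learning workflow.

The total loss is the sum of three terms — objectness (confidence),
classification and box regression — exactly:

    L = L_confidence + L_classification + L_box

Objectness and class terms are binary cross-entropy on logits; the box
term is complete-IoU between anchor-decoded predictions and their
assigned targets.  Targets are matched to anchors by the width/height
ratio test (max(r, 1/r) < 4) with up-to-two neighbouring grid cells,
the standard assigner of this detector family.  With a single class the
classification term is identically zero.

Evaluation: greedy one-to-one matching of detections to truths in
descending confidence at a given IoU threshold; average precision by
all-point interpolation of the precision envelope over recall; mAP50 at
IoU 0.5 and mAP95 as the IoU 0.50:0.95 average (the conventional form;
the literal single-threshold IoU=0.95 value is also available).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _imresize

from .autograd import Tensor, no_grad
from .data_io import Box, BoxAnnotationSet

__all__ = [
    "LossBreakdown", "EvalResult", "TrainSchedule", "compute_loss",
    "match_detections", "average_precision", "evaluate", "fit",
    "transfer_workflow", "save_checkpoint", "load_checkpoint", "nms",
]

# loss term gains and per-level objectness balance (P3, P4, P5)
BOX_GAIN, OBJ_GAIN, CLS_GAIN = 0.05, 1.0, 0.5
OBJ_BALANCE = (4.0, 1.0, 0.4)
ANCHOR_T = 4.0


@dataclass
class LossBreakdown:
    total: Tensor
    confidence: Tensor
    classification: Tensor
    box: Tensor

    def floats(self):
        return {k: float(getattr(self, k).data) for k in
                ("total", "confidence", "classification", "box")}


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    ap: float            # AP at the primary IoU threshold (0.5)
    map50: float
    map95: float         # IoU 0.50:0.95 average
    map95_strict: float  # literal single-threshold IoU = 0.95
    pr_curve: list       # (precision, recall) samples at IoU 0.5


# ----------------------------------------------------------------------
def _targets_array(annotations):
    """List of BoxAnnotationSet -> (n, 6) array (img, cls, x, y, w, h)."""
    rows = []
    for i, ann in enumerate(annotations):
        for b in ann.boxes:
            rows.append((i, b.cls, b.xc, b.yc, b.w, b.h))
    return np.array(rows, dtype=np.float32).reshape(-1, 6)


def _build_targets(shapes, targets, anchors, strides):
    """Anchor assignment per level.

    Returns, per level: (img, anchor, gj, gi) indices, xy offsets within
    the cell, wh targets in grid units, anchor wh in grid units, class.
    """
    out = []
    for (H, W), anc, stride in zip(shapes, anchors, strides):
        if len(targets) == 0:
            out.append(None)
            continue
        g = targets.copy()
        g[:, 2] *= W
        g[:, 3] *= H
        g[:, 4] *= W
        g[:, 5] *= H
        a_wh = anc / stride  # (3, 2) in grid units
        t_idx, a_idx = [], []
        for ai in range(len(a_wh)):
            r = g[:, 4:6] / a_wh[ai]
            keep = np.maximum(r, 1.0 / r).max(axis=1) < ANCHOR_T
            t_idx.append(np.where(keep)[0])
            a_idx.append(np.full(keep.sum(), ai))
        t_idx = np.concatenate(t_idx)
        a_idx = np.concatenate(a_idx)
        if len(t_idx) == 0:
            out.append(None)
            continue
        t = g[t_idx]
        gxy = t[:, 2:4]
        # centre cell plus up to two nearer neighbour cells (offset 0.5)
        offs = [np.zeros((len(t), 2))]
        fx, fy = gxy[:, 0] % 1, gxy[:, 1] % 1
        offs.append(np.stack([np.where((fx < 0.5) & (gxy[:, 0] > 1), -1.0, np.nan),
                              np.zeros(len(t))], axis=1))
        offs.append(np.stack([np.where((fx >= 0.5) & (gxy[:, 0] < W - 1), 1.0, np.nan),
                              np.zeros(len(t))], axis=1))
        offs.append(np.stack([np.zeros(len(t)),
                              np.where((fy < 0.5) & (gxy[:, 1] > 1), -1.0, np.nan)],
                             axis=1))
        offs.append(np.stack([np.zeros(len(t)),
                              np.where((fy >= 0.5) & (gxy[:, 1] < H - 1), 1.0, np.nan)],
                             axis=1))
        rows = []
        for off in offs:
            ok = ~np.isnan(off[:, 0]) & ~np.isnan(off[:, 1])
            if not ok.any():
                continue
            cell = np.floor(gxy[ok] + off[ok]).astype(int)
            rows.append((t_idx[ok], a_idx[ok], cell[:, 1], cell[:, 0],
                         gxy[ok] - cell, t[ok, 4:6], t[ok, 1].astype(int)))
        img = np.concatenate([g_[0] for g_ in rows])
        anc_i = np.concatenate([g_[1] for g_ in rows])
        gj = np.concatenate([g_[2] for g_ in rows])
        gi = np.concatenate([g_[3] for g_ in rows])
        txy = np.concatenate([g_[4] for g_ in rows])
        twh = np.concatenate([g_[5] for g_ in rows])
        cls = np.concatenate([g_[6] for g_ in rows])
        out.append(dict(img=targets[img.astype(int), 0].astype(int),
                        anchor=anc_i.astype(int), gj=gj, gi=gi,
                        txy=txy.astype(np.float32), twh=twh.astype(np.float32),
                        a_wh=a_wh[anc_i.astype(int)].astype(np.float32),
                        cls=cls))
    return out


def _ciou(pbox, tbox):
    """Complete IoU between (n, 4) centre-form Tensor boxes."""
    eps = 1e-7
    px, py, pw, ph = pbox[:, 0], pbox[:, 1], pbox[:, 2], pbox[:, 3]
    tx, ty = Tensor(tbox[:, 0]), Tensor(tbox[:, 1])
    tw, th = Tensor(np.maximum(tbox[:, 2], eps)), Tensor(np.maximum(tbox[:, 3], eps))
    p_x1, p_x2 = px - pw * 0.5, px + pw * 0.5
    p_y1, p_y2 = py - ph * 0.5, py + ph * 0.5
    t_x1, t_x2 = tx - tw * 0.5, tx + tw * 0.5
    t_y1, t_y2 = ty - th * 0.5, ty + th * 0.5
    iw = (p_x2.minimum(t_x2) - p_x1.maximum(t_x1)).clamp(0)
    ih = (p_y2.minimum(t_y2) - p_y1.maximum(t_y1)).clamp(0)
    inter = iw * ih
    union = pw * ph + tw * th - inter + eps
    iou = inter / union
    cw = p_x2.maximum(t_x2) - p_x1.minimum(t_x1)
    chh = p_y2.maximum(t_y2) - p_y1.minimum(t_y1)
    c2 = cw * cw + chh * chh + eps
    rho2 = (px - tx) ** 2 + (py - ty) ** 2
    v = (4.0 / math.pi ** 2) * ((tw / th).arctan() - (pw / (ph + eps)).arctan()) ** 2
    alpha = Tensor(v.data / (1.0 - iou.data + v.data + eps))  # detached
    return iou - rho2 / c2 - alpha * v


def compute_loss(predictions, targets, anchors, strides=(8, 16, 32)):
    """Anchor-assigned detection loss.

    ``predictions``: raw per-level maps from the detector (Tensors,
    shape (N, 3*(nc+5), H, W)).  ``targets``: list of
    BoxAnnotationSet, one per image.  ``anchors``: (3, 3, 2) pixel
    priors.  Returns a LossBreakdown whose total is the exact sum of
    the three terms.
    """
    anchors = np.asarray(anchors, dtype=np.float32).reshape(len(predictions), -1, 2)
    nc = predictions[0].shape[1] // 3 - 5
    shapes = [p.shape[-2:] for p in predictions]
    tarr = _targets_array(targets)
    assigned = _build_targets(shapes, tarr, anchors, strides)

    lbox = Tensor(0.0)
    lobj = Tensor(0.0)
    lcls = Tensor(0.0)
    for li, (p, asg, bal) in enumerate(zip(predictions, assigned, OBJ_BALANCE)):
        N, _, H, W = p.shape
        pv = p.reshape(N, 3, nc + 5, H, W).transpose(0, 1, 3, 4, 2)
        tobj = np.zeros((N, 3, H, W), dtype=np.float32)
        if asg is not None and len(asg["img"]):
            idx = (asg["img"], asg["anchor"], asg["gj"], asg["gi"])
            ps = pv[idx]                                   # (n, nc+5)
            pxy = ps[:, 0:2].sigmoid() * 2.0 - 0.5
            pwh = (ps[:, 2:4].sigmoid() * 2.0) ** 2 * Tensor(asg["a_wh"])
            from .autograd import concat
            pbox = concat([pxy, pwh], axis=1)
            tbox = np.concatenate([asg["txy"], asg["twh"]], axis=1)
            ciou = _ciou(pbox, tbox)
            lbox = lbox + (1.0 - ciou).mean()
            np.maximum.at(tobj, idx, np.clip(ciou.data, 0, 1))
            if nc > 1:
                tc = np.zeros((len(asg["cls"]), nc), dtype=np.float32)
                tc[np.arange(len(asg["cls"])), asg["cls"]] = 1.0
                lcls = lcls + ps[:, 5:].bce_with_logits(tc).mean()
        lobj = lobj + pv[..., 4].bce_with_logits(tobj).mean() * bal

    confidence = lobj * OBJ_GAIN
    classification = lcls * CLS_GAIN
    box = lbox * BOX_GAIN
    total = confidence + classification + box
    return LossBreakdown(total, confidence, classification, box)


# ----------------------------------------------------------------------
def _iou_matrix(a, b):
    """IoU between (n, 4) and (m, 4) centre-form pixel boxes."""
    if len(a) == 0 or len(b) == 0:
        return np.zeros((len(a), len(b)))
    ax1, ay1 = a[:, 0] - a[:, 2] / 2, a[:, 1] - a[:, 3] / 2
    ax2, ay2 = a[:, 0] + a[:, 2] / 2, a[:, 1] + a[:, 3] / 2
    bx1, by1 = b[:, 0] - b[:, 2] / 2, b[:, 1] - b[:, 3] / 2
    bx2, by2 = b[:, 0] + b[:, 2] / 2, b[:, 1] + b[:, 3] / 2
    iw = np.clip(np.minimum(ax2[:, None], bx2) - np.maximum(ax1[:, None], bx1), 0, None)
    ih = np.clip(np.minimum(ay2[:, None], by2) - np.maximum(ay1[:, None], by1), 0, None)
    inter = iw * ih
    union = (a[:, 2] * a[:, 3])[:, None] + b[:, 2] * b[:, 3] - inter
    return inter / np.maximum(union, 1e-12)


def match_detections(detections, truths, iou_threshold=0.5):
    """Greedy one-to-one matching in descending confidence.

    ``detections``: (n, 5) array (xc, yc, w, h, score); ``truths``:
    (m, 4).  Returns (TP, FP, FN, tp_flags) where tp_flags marks each
    detection in the *score-sorted* order.
    """
    detections = np.asarray(detections, dtype=float).reshape(-1, 5)
    truths = np.asarray(truths, dtype=float).reshape(-1, 4)
    order = np.argsort(-detections[:, 4], kind="stable")
    dets = detections[order]
    iou = _iou_matrix(dets[:, :4], truths)
    taken = np.zeros(len(truths), dtype=bool)
    flags = np.zeros(len(dets), dtype=bool)
    for i in range(len(dets)):
        if len(truths) == 0:
            break
        cand = np.where(~taken & (iou[i] >= iou_threshold))[0]
        if len(cand):
            j = cand[np.argmax(iou[i][cand])]
            taken[j] = True
            flags[i] = True
    tp = int(flags.sum())
    return tp, int(len(dets) - tp), int(len(truths) - tp), flags


def average_precision(pr_samples):
    """All-point interpolated AP from (precision, recall) samples.

    The precision envelope (running maximum from high recall down) is
    integrated over recall, with an implicit (p, r=0) start point.
    """
    pts = sorted((float(r), float(p)) for p, r in pr_samples)
    recalls = np.array([r for r, _ in pts])
    precs = np.array([p for _, p in pts])
    env = np.maximum.accumulate(precs[::-1])[::-1]
    ap, prev_r = 0.0, 0.0
    for r, p in zip(recalls, env):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def nms(boxes, scores, iou_threshold=0.45):
    """Indices kept by class-agnostic non-maximum suppression."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    while len(order):
        i = order[0]
        keep.append(i)
        if len(order) == 1:
            break
        rest = order[1:]
        iou = _iou_matrix(boxes[i:i + 1], boxes[rest])[0]
        order = rest[iou <= iou_threshold]
    return np.array(keep, dtype=int)


def _ap_at(per_image, iou_thr):
    """Dataset AP at one IoU threshold from per-image (dets, truths)."""
    flags_all, scores_all, n_truth = [], [], 0
    for dets, truths in per_image:
        n_truth += len(truths)
        if len(dets) == 0:
            continue
        *_, flags = match_detections(dets, truths, iou_thr)
        order = np.argsort(-dets[:, 4], kind="stable")
        flags_all.append(flags)
        scores_all.append(dets[order, 4])
    if n_truth == 0:
        raise ValueError("no ground-truth objects: recall undefined")
    if not flags_all:
        return 0.0, []
    flags = np.concatenate(flags_all)
    scores = np.concatenate(scores_all)
    order = np.argsort(-scores, kind="stable")
    flags = flags[order]
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / n_truth
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1e-12)
    samples = list(zip(precision.tolist(), recall.tolist()))
    return average_precision(samples), samples


def evaluate(samples, model, conf=0.001, nms_iou=0.45, count_conf=0.25,
             img_size=None):
    """Run the detector over (image, annotations) samples and score it.

    Images are (H, W, C) arrays in [0, 1] (or uint8); annotations are
    BoxAnnotationSet.  TP/FP/FN counts are reported at the
    visualisation confidence ``count_conf``; the PR curve and AP use
    every detection above ``conf``.
    """
    model.eval()
    per_image = []
    for image, ann in samples:
        img, _ = _prepare_image(image, img_size or _default_size(image))
        with no_grad():
            raw = model(img[None])
        dets = model.detect.decode(raw)[0]
        boxes = dets[:, :4]
        scores = dets[:, 4] * dets[:, 5]
        m = scores >= conf
        boxes, scores = boxes[m], scores[m]
        if len(boxes):
            keep = nms(boxes, scores, nms_iou)
            boxes, scores = boxes[keep], scores[keep]
        h, w = img.shape[1:]
        truths = np.array([[b.xc * w, b.yc * h, b.w * w, b.h * h]
                           for b in ann.boxes]).reshape(-1, 4)
        per_image.append((np.concatenate([boxes, scores[:, None]], axis=1)
                          if len(boxes) else np.zeros((0, 5)), truths))
    ap50, curve = _ap_at(per_image, 0.50)
    aps = [ap50] + [_ap_at(per_image, t)[0]
                    for t in np.arange(0.55, 0.96, 0.05)]
    ap95_strict = aps[-1]
    tp = fp = fn = 0
    for dets, truths in per_image:
        strong = dets[dets[:, 4] >= count_conf]
        t, f, n, _ = match_detections(strong, truths, 0.5)
        tp, fp, fn = tp + t, fp + f, fn + n
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    return EvalResult(tp, fp, fn, prec, rec, ap50, ap50,
                      float(np.mean(aps)), ap95_strict, curve)


# ----------------------------------------------------------------------
@dataclass
class TrainSchedule:
    """The published training recipe, every knob overridable."""

    epochs: int = 300
    iterations: int = None        # overrides epochs when set
    batch_size: int = 4
    img_size: int = 640
    lr0: float = 1e-2
    lrf: float = 1e-5
    momentum: float = 0.937
    warmup_momentum: float = 0.8
    warmup_epochs: int = 3
    weight_decay: float = 5e-3
    hflip: bool = True
    rotate: bool = True
    color: bool = True
    mosaic: bool = True
    rotate_degrees: float = 10.0
    seed: int = 0


def _default_size(image):
    return 32 * max(1, round(max(image.shape[:2]) / 32))


def _prepare_image(image, size):
    """HWC (or HW) image -> CHW float32 square of side ``size``."""
    arr = np.asarray(image)
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float32) / 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(np.float32) / 65535.0
    if arr.ndim == 2:
        arr = arr[..., None].repeat(3, axis=2)
    if arr.shape[:2] != (size, size):
        arr = _imresize(arr, (size, size), order=1, preserve_range=True,
                        anti_aliasing=False)
    return arr.transpose(2, 0, 1).astype(np.float32), (size, size)


def _augment(img_chw, boxes, rng, sched):
    """Seeded online augmentation on one CHW image + normalised boxes."""
    from scipy import ndimage as ndi
    img = img_chw
    boxes = list(boxes)
    if sched.hflip and rng.random() < 0.5:
        img = img[:, :, ::-1].copy()
        boxes = [Box(b.cls, 1.0 - b.xc, b.yc, b.w, b.h) for b in boxes]
    if sched.color and rng.random() < 0.8:
        gains = rng.uniform(0.8, 1.2, size=(img.shape[0], 1, 1)).astype(np.float32)
        img = np.clip(img * gains, 0, 1)
    if sched.rotate and rng.random() < 0.5:
        deg = rng.uniform(-sched.rotate_degrees, sched.rotate_degrees)
        img = np.stack([ndi.rotate(c, deg, reshape=False, order=1, mode="nearest")
                        for c in img])
        th = math.radians(deg)
        S = img.shape[1]
        co, si = math.cos(th), math.sin(th)
        out = []
        for b in boxes:
            cx, cy = (b.xc - 0.5) * S, (b.yc - 0.5) * S
            # rotate corners, take the enclosing box
            w2, h2 = b.w * S / 2, b.h * S / 2
            xs, ys = [], []
            for dx, dy in ((w2, h2), (-w2, h2), (w2, -h2), (-w2, -h2)):
                xs.append(cx * co + cy * si + dx)
                ys.append(-cx * si + cy * co + dy)
            x0, x1 = max(min(xs), -S / 2), min(max(xs), S / 2)
            y0, y1 = max(min(ys), -S / 2), min(max(ys), S / 2)
            if x1 - x0 < 1 or y1 - y0 < 1:
                continue
            out.append(Box(b.cls, (x0 + x1) / 2 / S + 0.5, (y0 + y1) / 2 / S + 0.5,
                           (x1 - x0) / S, (y1 - y0) / S))
        boxes = out
    return img, boxes


def _mosaic(samples, idxs, size, rng, sched):
    """Compose 4 source frames into one 2x2 training image with
    remapped boxes."""
    canvas = np.zeros((3, size, size), dtype=np.float32)
    boxes = []
    half = size // 2
    for k, (qy, qx) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
        image, ann = samples[idxs[k]]
        img, _ = _prepare_image(image, half)
        canvas[:, qy * half:(qy + 1) * half, qx * half:(qx + 1) * half] = img
        for b in ann.boxes:
            boxes.append(Box(b.cls, (b.xc + qx) / 2.0, (b.yc + qy) / 2.0,
                             b.w / 2.0, b.h / 2.0))
    return canvas, boxes


class _SGD:
    """SGD with momentum and decoupled weight decay on kernels only."""

    def __init__(self, model):
        self.params = []
        for name, p in model.named_parameters():
            decay = name.endswith("weight") and p.data.ndim > 1
            self.params.append((p, decay, np.zeros_like(p.data)))

    def step(self, lr, momentum, weight_decay):
        for p, decay, v in self.params:
            if p.grad is None:
                continue
            g = p.grad
            if decay:
                g = g + weight_decay * p.data
            v *= momentum
            v += g
            p.data -= lr * v


def fit(model, samples, schedule=None, log_every=1, eval_samples=None):
    """Train a detector on (image, BoxAnnotationSet) samples.

    SGD with momentum warm-up (0.8 -> momentum over the warm-up phase),
    cosine learning-rate decay lr0 -> lrf, weight decay on convolution
    kernels; online augmentations (horizontal flip, random rotation,
    colour change, mosaic), each toggleable.  Returns (model, logs); the
    best (lowest-loss) weights are kept on the model at the end.
    """
    sched = schedule or TrainSchedule()
    rng = np.random.default_rng(sched.seed)
    n = len(samples)
    if n == 0:
        raise ValueError("empty dataset")
    iters_per_epoch = max(n // sched.batch_size, 1)
    total_iters = (sched.iterations if sched.iterations
                   else sched.epochs * iters_per_epoch)
    warmup_iters = min(sched.warmup_epochs * iters_per_epoch, total_iters // 3)
    opt = _SGD(model)
    model.train()
    anchors = model.detect.anchors
    logs = []
    best = (np.inf, None)
    for it in range(total_iters):
        # schedule
        if it < warmup_iters and warmup_iters > 0:
            f = it / warmup_iters
            lr = sched.lr0 * f
            mom = sched.warmup_momentum + f * (sched.momentum - sched.warmup_momentum)
        else:
            t = (it - warmup_iters) / max(total_iters - warmup_iters, 1)
            lr = sched.lrf + 0.5 * (sched.lr0 - sched.lrf) * (1 + math.cos(math.pi * t))
            mom = sched.momentum
        # minibatch
        imgs, anns = [], []
        for _ in range(sched.batch_size):
            if sched.mosaic and rng.random() < 0.5 and n >= 4:
                img, boxes = _mosaic(samples, rng.integers(0, n, 4),
                                     sched.img_size, rng, sched)
            else:
                image, ann = samples[int(rng.integers(0, n))]
                img, _ = _prepare_image(image, sched.img_size)
                boxes = list(ann.boxes)
            img, boxes = _augment(img, boxes, rng, sched)
            imgs.append(img)
            anns.append(BoxAnnotationSet("b", sched.img_size, sched.img_size,
                                         boxes))
        x = Tensor(np.stack(imgs))
        preds = model(x)
        loss = compute_loss(preds, anns, anchors)
        model.zero_grad()
        loss.total.backward()
        if not np.isfinite(loss.total.data):
            raise RuntimeError(f"divergence at iteration {it}: loss={loss.floats()}")
        opt.step(lr, mom, sched.weight_decay)
        rec = {"iter": it, "lr": lr, **loss.floats()}
        logs.append(rec)
        if rec["total"] < best[0]:
            best = (rec["total"], model.state_dict())
    if best[1] is not None:
        model.load_state_dict(best[1])
    return model, logs


def validation_loss(model, samples, img_size, batch=None):
    """Loss breakdown on a held-out set, no parameter updates."""
    model.train()  # batch statistics, but no update
    imgs, anns = [], []
    for image, ann in (samples if batch is None else samples[:batch]):
        img, _ = _prepare_image(image, img_size)
        imgs.append(img)
        anns.append(ann)
    x = Tensor(np.stack(imgs))
    preds = model(x)
    loss = compute_loss(preds, anns, model.detect.anchors)
    model.zero_grad()
    return loss


def transfer_workflow(source_samples, target_samples, build, schedule,
                      finetune_schedule=None):
    """Scale-matched transfer learning.

    Train a detector on the (already scale-matched) source corpus, then
    use its best weights to initialise training on the target corpus;
    the comparison of interest is the first-iteration validation box
    loss under pretrained vs. random initialisation.

    ``build``: zero-argument factory returning a freshly initialised
    model (architectures must match for the checkpoint hand-off).
    Returns a dict with the pretrained model, the fine-tuned model, the
    two first-iteration validation box losses and both loss traces.
    """
    src_model, src_logs = fit(build(), source_samples, schedule)
    pretrained_sd = src_model.state_dict()

    fresh = build()
    box_random = float(validation_loss(
        fresh, target_samples, schedule.img_size).box.data)
    warm = build()
    warm.load_state_dict(pretrained_sd)
    box_pretrained = float(validation_loss(
        warm, target_samples, schedule.img_size).box.data)

    ft_sched = finetune_schedule or schedule
    warm, ft_logs = fit(warm, target_samples, ft_sched)
    return {
        "source_model": src_model,
        "finetuned_model": warm,
        "box_loss_random_init": box_random,
        "box_loss_pretrained_init": box_pretrained,
        "source_logs": src_logs,
        "finetune_logs": ft_logs,
    }


# ----------------------------------------------------------------------
def save_checkpoint(model, path):
    """Single-file weight archive with the embedded model config."""
    payload = {f"param/{k}": v for k, v in model.state_dict().items()}
    payload["config_yaml"] = np.array(model.config.to_yaml())
    np.savez(path, **payload)


def load_checkpoint(path, build=None):
    """Rebuild a detector from a checkpoint written by save_checkpoint."""
    from .model_zoo import ModelConfig, build_detector
    data = np.load(path, allow_pickle=False)
    cfg = ModelConfig.from_yaml(str(data["config_yaml"]))
    model = build(cfg) if build else build_detector(cfg)
    model.load_state_dict({k[len("param/"):]: data[k]
                           for k in data.files if k.startswith("param/")})
    return model
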