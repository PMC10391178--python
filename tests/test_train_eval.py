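"""Loss construction, detection metrics against independent oracles,
and the training loop's contracts."""
import math

import networkx as nx
import numpy as np
import pytest

from teadet.autograd import Tensor
from teadet.data_io import Box, BoxAnnotationSet
from teadet.model_zoo import build_detector, preset_config
from teadet.train_eval import (OBJ_BALANCE, TrainSchedule, _ap_at,
                               _build_targets, _mosaic, average_precision,
                               compute_loss, evaluate, fit, match_detections,
                               load_checkpoint, save_checkpoint,
                               transfer_workflow, validation_loss)

ANCHORS = np.array([[10, 13, 16, 30, 33, 23],
                    [30, 61, 62, 45, 59, 119],
                    [116, 90, 156, 198, 373, 326]], dtype=np.float32)


def _zero_preds(size=64, n=1):
    return [Tensor(np.zeros((n, 18, size // s, size // s), dtype=np.float32))
            for s in (8, 16, 32)]


# ------------------------------------------------------------------ loss
def test_empty_targets_zero_logits_closed_form():
    preds = _zero_preds()
    lb = compute_loss(preds, [BoxAnnotationSet("x", 64, 64, [])], ANCHORS)
    assert float(lb.classification.data) == 0.0
    assert float(lb.box.data) == 0.0
    # every cell carries BCE(logit 0, target 0) = log 2, balance-weighted
    expect = math.log(2.0) * sum(OBJ_BALANCE)
    assert float(lb.confidence.data) == pytest.approx(expect, rel=1e-6)


def test_breakdown_additivity_on_random_fixtures(rng, tiny_corpus):
    imgs, anns = zip(*tiny_corpus[:2])
    preds = [Tensor(rng.normal(size=(2, 18, 64 // s, 64 // s)).astype(np.float32))
             for s in (8, 16, 32)]
    lb = compute_loss(preds, list(anns), ANCHORS)
    # exact in the working precision: the total IS the float32 sum
    total = lb.confidence.data + lb.classification.data + lb.box.data
    assert lb.total.data == total
    assert min(float(lb.confidence.data), float(lb.box.data)) >= 0


def test_perfect_prediction_has_negligible_loss():
    """Inject the targets as predictions (exact inverse-sigmoid logits,
    saturated objectness): the loss collapses."""
    size = 64
    ann = BoxAnnotationSet("x", size, size,
                           [Box(0, 0.55, 0.42, 10 / size, 13 / size),
                            Box(0, 0.30, 0.68, 30 / size, 61 / size)])
    targets = np.array([[0, 0, b.xc, b.yc, b.w, b.h] for b in ann.boxes],
                       dtype=np.float32)
    shapes = [(size // s, size // s) for s in (8, 16, 32)]
    asg = _build_targets(shapes, targets, ANCHORS.reshape(3, 3, 2), (8, 16, 32))
    preds = []
    def logit(p):
        p = np.clip(p, 1e-6, 1 - 1e-6)
        return np.log(p / (1 - p))
    for (H, W), a in zip(shapes, asg):
        raw = np.full((1, 3, 6, H, W), 0.0, dtype=np.float32)
        raw[:, :, 4] = -15.0
        if a is not None and len(a["img"]):
            sx = logit((a["txy"] + 0.5) / 2.0)
            sw = logit(0.5 * np.sqrt(a["twh"] / a["a_wh"]))
            for k in range(len(a["img"])):
                i, j, anc = a["gj"][k], a["gi"][k], a["anchor"][k]
                raw[0, anc, 0, i, j] = sx[k, 0]
                raw[0, anc, 1, i, j] = sx[k, 1]
                raw[0, anc, 2, i, j] = sw[k, 0]
                raw[0, anc, 3, i, j] = sw[k, 1]
                raw[0, anc, 4, i, j] = 15.0
        preds.append(Tensor(raw.reshape(1, 18, H, W)))
    lb = compute_loss(preds, [ann], ANCHORS)
    assert float(lb.total.data) < 1e-3


# --------------------------------------------------------------- matching
def _oracle_max_matching(dets, truths, thr):
    """Independent oracle: maximum bipartite matching over IoU >= thr."""
    from teadet.train_eval import _iou_matrix
    iou = _iou_matrix(dets[:, :4], truths)
    g = nx.Graph()
    g.add_nodes_from([("d", i) for i in range(len(dets))])
    g.add_nodes_from([("t", j) for j in range(len(truths))])
    for i in range(len(dets)):
        for j in range(len(truths)):
            if iou[i, j] >= thr:
                g.add_edge(("d", i), ("t", j))
    m = nx.algorithms.matching.max_weight_matching(g, maxcardinality=True)
    return len(m)


def test_identical_detections_are_all_true_positives(rng):
    t = rng.uniform(10, 90, (6, 4))
    t[:, 2:] = rng.uniform(5, 12, (6, 2))
    d = np.concatenate([t, rng.uniform(0.5, 1, (6, 1))], axis=1)
    tp, fp, fn, _ = match_detections(d, t, 0.5)
    assert (tp, fp, fn) == (6, 0, 0)


def test_precision_recall_arithmetic_example(rng):
    """10 truths, 8 matched detections + 2 spurious -> (8, 2, 2)."""
    gx, gy = np.meshgrid(np.arange(5), np.arange(2))
    truths = np.stack([20 + 40 * gx.ravel(), 20 + 40 * gy.ravel(),
                       np.full(10, 10.0), np.full(10, 10.0)], axis=1)
    dets = np.concatenate([truths[:8], rng.uniform(0.5, 1, (8, 1))], axis=1)
    spurious = np.array([[200, 200, 10, 10, 0.9], [220, 220, 10, 10, 0.8]])
    dets = np.concatenate([dets, spurious])
    tp, fp, fn, _ = match_detections(dets, truths, 0.5)
    assert (tp, fp, fn) == (8, 2, 2)
    assert tp / (tp + fp) == pytest.approx(0.8)
    assert tp / (tp + fn) == pytest.approx(0.8)


@pytest.mark.parametrize("seed", range(8))
def test_matching_equals_exhaustive_oracle_on_small_instances(seed):
    """Randomised instances (<= 8 boxes, separated so overlap structure
    is unambiguous) match the exhaustive maximum-matching count."""
    rng = np.random.default_rng(seed)
    n_t, n_d = rng.integers(1, 8, 2)
    cell = rng.permutation(16)[:n_t]
    truths = np.stack([20.0 * (cell % 4) + 10, 20.0 * (cell // 4) + 10,
                       np.full(n_t, 8.0), np.full(n_t, 8.0)], axis=1)
    dets = []
    for i in range(n_d):
        if i < n_t and rng.random() < 0.7:
            base = truths[i, :2] + rng.uniform(-2, 2, 2)
        else:
            base = rng.uniform(100, 200, 2)
        dets.append([*base, 8.0, 8.0, rng.uniform(0.1, 1.0)])
    dets = np.array(dets)
    tp, fp, fn, _ = match_detections(dets, truths, 0.5)
    assert tp == _oracle_max_matching(dets, truths, 0.5)
    assert fp == len(dets) - tp and fn == n_t - tp


# --------------------------------------------------------------------- AP
def test_average_precision_hand_cases():
    assert average_precision([(1.0, 1.0)]) == 1.0
    assert average_precision([(1.0, 0.5), (0.5, 1.0)]) == pytest.approx(0.75)


def test_ap_invariant_to_detection_order(rng, small_scene):
    _, ann = small_scene
    h, w = 128, 160
    truths = np.array([[b.xc * w, b.yc * h, b.w * w, b.h * h]
                       for b in ann.boxes])
    dets = np.concatenate([truths + rng.normal(0, 1, truths.shape),
                           rng.uniform(0.05, 1, (len(truths), 1))], axis=1)
    ap1, _ = _ap_at([(dets, truths)], 0.5)
    ap2, _ = _ap_at([(dets[rng.permutation(len(dets))], truths)], 0.5)
    assert ap1 == pytest.approx(ap2, abs=1e-12)


def _coco_style_ap(per_image, thr):
    """Independent reference evaluator: greedy score-ordered matching
    and 101-point interpolated AP (COCO convention)."""
    scores, flags, n_truth = [], [], 0
    for dets, truths in per_image:
        n_truth += len(truths)
        order = np.argsort(-dets[:, 4], kind="stable")
        taken = np.zeros(len(truths), bool)
        from teadet.train_eval import _iou_matrix
        iou = _iou_matrix(dets[order, :4], truths)
        for k in range(len(order)):
            js = np.where(~taken & (iou[k] >= thr))[0]
            hit = False
            if len(js):
                j = js[np.argmax(iou[k, js])]
                taken[j] = True
                hit = True
            flags.append(hit)
            scores.append(dets[order[k], 4])
    order = np.argsort(-np.asarray(scores), kind="stable")
    f = np.asarray(flags)[order]
    tp = np.cumsum(f)
    fp = np.cumsum(~f)
    rec = tp / n_truth
    prec = tp / np.maximum(tp + fp, 1e-12)
    # precision envelope sampled at 101 recall points
    out = 0.0
    for r in np.linspace(0, 1, 101):
        p = prec[rec >= r]
        out += (p.max() if len(p) else 0.0) / 101
    return out


def test_ap_agrees_with_coco_style_reference(rng):
    per_image = []
    for s in range(4):
        from teadet.synthetic import SceneConfig, generate_scene
        _, ann = generate_scene(SceneConfig(width=160, height=128,
                                            n_objects=(15, 25),
                                            mean_rel_scale=0.08), seed=70 + s)
        h, w = 128, 160
        truths = np.array([[b.xc * w, b.yc * h, b.w * w, b.h * h]
                           for b in ann.boxes])
        jit = truths + rng.normal(0, 1.2, truths.shape)
        keep = rng.random(len(jit)) < 0.8
        dets = np.concatenate([jit[keep],
                               rng.uniform(0.3, 1, (keep.sum(), 1))], axis=1)
        spurious = np.concatenate([rng.uniform(5, 120, (5, 2)),
                                   rng.uniform(4, 10, (5, 2)),
                                   rng.uniform(0.3, 1, (5, 1))], axis=1)
        per_image.append((np.concatenate([dets, spurious]), truths))
    ours, _ = _ap_at(per_image, 0.5)
    ref = _coco_style_ap(per_image, 0.5)
    assert ours == pytest.approx(ref, abs=0.01)


def test_evaluate_rejects_truthless_dataset(tiny_corpus):
    model = build_detector(preset_config("improved", img_size=64))
    img, _ = tiny_corpus[0]
    empty = BoxAnnotationSet("e", 128, 128, [])
    with pytest.raises(ValueError):
        evaluate([(img, empty)], model, img_size=64)


# ------------------------------------------------------------------ fit
def test_mosaic_composes_four_frames_with_remapped_boxes(tiny_corpus):
    sched = TrainSchedule(img_size=128)
    rng = np.random.default_rng(0)
    canvas, boxes = _mosaic(tiny_corpus, [0, 1, 2, 3], 128, rng, sched)
    assert canvas.shape == (3, 128, 128)
    n_src = sum(len(tiny_corpus[i][1]) for i in range(4))
    assert len(boxes) == n_src
    # quadrant k's boxes land in quadrant k with halved size
    for k, (qy, qx) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
        src = tiny_corpus[k][1].boxes
        off = sum(len(tiny_corpus[i][1]) for i in range(k))
        for b_src, b_out in zip(src, boxes[off:off + len(src)]):
            assert b_out.xc == pytest.approx((b_src.xc + qx) / 2)
            assert b_out.yc == pytest.approx((b_src.yc + qy) / 2)
            assert b_out.w == pytest.approx(b_src.w / 2)


def test_fixed_seed_without_augmentation_is_deterministic(tiny_corpus):
    sched = TrainSchedule(iterations=3, batch_size=2, img_size=64, seed=9,
                          hflip=False, rotate=False, color=False, mosaic=False)
    traces = []
    for _ in range(2):
        model = build_detector(preset_config("improved", img_size=64),
                               rng=np.random.default_rng(5))
        _, logs = fit(model, tiny_corpus, sched)
        traces.append([l["total"] for l in logs])
    assert traces[0] == traces[1]


def test_divergence_aborts_with_diagnostics(tiny_corpus):
    model = build_detector(preset_config("improved", img_size=64))
    model.backbone[0].conv.weight.data[:] = np.nan
    sched = TrainSchedule(iterations=1, batch_size=1, img_size=64,
                          mosaic=False, rotate=False)
    with pytest.raises(RuntimeError, match="divergence"):
        fit(model, tiny_corpus, sched)


def test_checkpoint_round_trip_preserves_evaluation(tmp_path, tiny_corpus):
    model = build_detector(preset_config("improved", img_size=64))
    r1 = evaluate(tiny_corpus[:2], model, img_size=64)
    save_checkpoint(model, tmp_path / "w.npz")
    back = load_checkpoint(tmp_path / "w.npz")
    r2 = evaluate(tiny_corpus[:2], back, img_size=64)
    assert (r1.tp, r1.fp, r1.fn, r1.map50) == (r2.tp, r2.fp, r2.fn, r2.map50)


def test_checkpoint_architecture_mismatch_rejected(tmp_path):
    model = build_detector(preset_config("improved"))
    save_checkpoint(model, tmp_path / "w.npz")
    other = build_detector(preset_config("baseline"))
    with pytest.raises(ValueError):
        other.load_state_dict(model.state_dict())


def test_transfer_workflow_warm_start_sanity(tiny_corpus):
    """Identical source and target: fine-tuning from the source weights
    must not end above the source's own final training loss range."""
    sched = TrainSchedule(iterations=8, batch_size=2, img_size=64, seed=3,
                          mosaic=False, rotate=False)
    build = lambda: build_detector(preset_config("improved", img_size=64),
                                   rng=np.random.default_rng(3))
    res = transfer_workflow(tiny_corpus[:3], tiny_corpus[:3], build, sched,
                            finetune_schedule=TrainSchedule(
                                iterations=4, batch_size=2, img_size=64,
                                seed=3, mosaic=False, rotate=False))
    assert res["box_loss_pretrained_init"] >= 0
    assert res["finetune_logs"][-1]["total"] <= 1.5 * res["source_logs"][-1]["total"]
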