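"""Detection metrics against hand arithmetic and a brute-force evaluator."""

import numpy as np
import pytest

from avidet.boxloss import BoundingBox, iou
from avidet.evalkit import (Detection, GroundTruth, IOU_RANGE,
                            average_precision, confusion_matrix, map_range,
                            match_detections, precision_recall)

B = BoundingBox.from_corners


def det(img, cls, box, conf):
    return Detection(img, cls, box, conf)


def gt(img, cls, box):
    return GroundTruth(img, cls, box)


# ------------------------------------------------------- brute-force oracle
def brute_force_eval(dets, gts, thresholds=IOU_RANGE):
    """Naive reference evaluator: explicit loops and explicit envelope."""
    classes = sorted({g.class_id for g in gts} | {d.class_id for d in dets})
    ap_by_cls = {}
    for cls in classes:
        ngt = sum(1 for g in gts if g.class_id == cls)
        aps = []
        for t in thresholds:
            order = sorted((d for d in dets if d.class_id == cls),
                           key=lambda d: -d.confidence)
            used = set()
            flags = []
            for d in order:
                cands = [(j, g) for j, g in enumerate(gts)
                         if g.class_id == cls and g.image_id == d.image_id
                         and j not in used]
                best_j, best_v = None, 0.0
                for j, g in cands:
                    v = iou(d.box, g.box)
                    if v > best_v:
                        best_j, best_v = j, v
                if best_j is not None and best_v >= t:
                    used.add(best_j)
                    flags.append(1)
                else:
                    flags.append(0)
            if ngt == 0:
                aps.append(0.0)
                continue
            tp = fp = 0
            pr = []
            for f in flags:
                tp += f
                fp += 1 - f
                pr.append((tp / ngt, tp / (tp + fp)))
            ap = 0.0
            for k in range(101):
                r = k / 100.0
                cand = [p for (rr, p) in pr if rr >= r - 1e-12]
                ap += max(cand) if cand else 0.0
            aps.append(ap / 101.0)
        ap_by_cls[cls] = aps
    return ap_by_cls


def random_problem(rng):
    imgs = [f"im{k}" for k in range(rng.integers(1, 4))]
    classes = list(range(rng.integers(1, 4)))
    gts, dets = [], []
    for im in imgs:
        for _ in range(rng.integers(0, 5)):
            x, y = rng.uniform(0, 80, 2)
            w, h = rng.uniform(5, 30, 2)
            c = int(rng.choice(classes))
            gts.append(gt(im, c, BoundingBox(x, y, w, h)))
            # jittered detection of the same object, sometimes
            if rng.random() < 0.8:
                dx, dy = rng.normal(0, 6, 2)
                dets.append(det(im, int(rng.choice(classes)),
                                BoundingBox(x + dx, y + dy,
                                            w * rng.uniform(0.6, 1.4),
                                            h * rng.uniform(0.6, 1.4)),
                                float(rng.uniform(0.05, 1.0))))
        for _ in range(rng.integers(0, 3)):  # spurious
            x, y = rng.uniform(0, 80, 2)
            dets.append(det(im, int(rng.choice(classes)),
                            BoundingBox(x, y, *rng.uniform(5, 30, 2)),
                            float(rng.uniform(0.05, 1.0))))
    if not gts:
        gts.append(gt(imgs[0], classes[0], BoundingBox(10, 10, 5, 5)))
    return dets, gts, classes


# ------------------------------------------------------------------ matching
def test_match_single_tp():
    g = [gt("a", 0, B(0, 0, 10, 10))]
    d = [det("a", 0, B(0, 0, 10, 6), 0.9)]  # IoU 0.6
    _, flags, matched = match_detections(d, g, 0.5)
    assert flags == [True] and matched == [True]


def test_match_duplicate_detection_is_fp():
    g = [gt("a", 0, B(0, 0, 10, 10))]
    d = [det("a", 0, B(0, 0, 10, 9), 0.6),
         det("a", 0, B(0, 0, 10, 10), 0.9)]
    order, flags, _ = match_detections(d, g, 0.5)
    assert order == [1, 0]
    assert flags == [True, False]  # higher confidence claims the gt


def test_match_no_detections_all_fn():
    g = [gt("a", 0, B(0, 0, 1, 1)), gt("a", 0, B(5, 5, 6, 6))]
    _, flags, matched = match_detections([], g, 0.5)
    assert flags == [] and matched == [False, False]


# ------------------------------------------------------------------- scalars
@pytest.mark.parametrize("tp,fp,fn,expected", [
    (2, 1, 0, (2 / 3, 1.0)),
    (5, 0, 0, (1.0, 1.0)),
    (0, 0, 3, (0.0, 0.0)),
    (0, 0, 0, (0.0, 0.0)),
])
def test_precision_recall_values(tp, fp, fn, expected):
    assert precision_recall(tp, fp, fn) == pytest.approx(expected)


def test_precision_recall_rejects_negative():
    with pytest.raises(ValueError):
        precision_recall(-1, 0, 0)


@pytest.mark.parametrize("flags,ngt,expected", [
    ([True], 1, 1.0),
    ([True, False, True], 2, (51 * 1.0 + 50 * (2 / 3)) / 101),
    ([False, False], 3, 0.0),
])
def test_average_precision_101point(flags, ngt, expected):
    assert average_precision(flags, ngt) == pytest.approx(expected, abs=1e-12)


def test_average_precision_rejects_flags_without_gt():
    with pytest.raises(ValueError):
        average_precision([True], 0)


# ----------------------------------------------------------------- map_range
def test_map_range_single_detection_threshold_sweep():
    """IoU exactly 0.6 passes thresholds 0.50/0.55/0.60 -> mAP@0.5:0.95 = 0.3."""
    g = [gt("a", 0, B(0, 0, 10, 10))]
    d = [det("a", 0, B(0, 2.5, 10, 12.5), 0.9)]  # inter 75, union 125
    assert iou(d[0].box, g[0].box) == 0.6
    res = map_range(d, g)
    assert res.map50 == pytest.approx(1.0)
    assert res.map50_95 == pytest.approx(0.3, abs=1e-12)


def test_map_perfect_detections():
    gts = [gt("a", c, B(10 * c, 0, 10 * c + 5, 5)) for c in range(3)]
    dets = [det(g.image_id, g.class_id, g.box, 0.9) for g in gts]
    res = map_range(dets, gts)
    assert res.map50 == 1.0 and res.map50_95 == 1.0
    assert all(res.precision[c] == 1.0 and res.recall[c] == 1.0
               for c in res.class_ids)


def test_map_range_monotone_in_threshold(rng):
    for _ in range(10):
        dets, gts, _ = random_problem(rng)
        res = map_range(dets, gts)
        assert res.map50_95 <= res.map50 + 1e-12


def test_ap_invariant_to_confidence_rescaling(rng):
    dets, gts, _ = random_problem(rng)
    res1 = map_range(dets, gts)
    scaled = [Detection(d.image_id, d.class_id, d.box, d.confidence * 0.5)
              for d in dets]
    res2 = map_range(scaled, gts)
    assert res1.map50 == pytest.approx(res2.map50, abs=1e-12)
    assert res1.map50_95 == pytest.approx(res2.map50_95, abs=1e-12)


def test_map_range_matches_brute_force(rng):
    """Implementation vs naive double-loop evaluator on random problems."""
    for _ in range(40):
        dets, gts, _ = random_problem(rng)
        res = map_range(dets, gts)
        ref = brute_force_eval(dets, gts)
        for cls, aps in ref.items():
            assert res.ap50[cls] == pytest.approx(aps[0], abs=1e-9)
            assert res.ap[cls] == pytest.approx(np.mean(aps), abs=1e-9)


# ---------------------------------------------------------- confusion matrix
def test_confusion_perfect():
    gts = [gt("a", c, B(20 * c, 0, 20 * c + 10, 10)) for c in range(3)]
    dets = [det(g.image_id, g.class_id, g.box, 0.9) for g in gts]
    m = confusion_matrix(dets, gts, num_classes=3)
    assert np.array_equal(m[:3, :3], np.eye(3))
    assert m[3].sum() == 0 and m[:, 3].sum() == 0


def test_confusion_miss_and_spurious():
    gts = [gt("a", 2, B(0, 0, 10, 10))]
    dets = [det("a", 1, B(50, 50, 60, 60), 0.9)]  # spurious class-1
    m = confusion_matrix(dets, gts, num_classes=3)
    assert m[3, 2] == 1  # missed gt of class 2 -> (background, true=2)
    assert m[1, 3] == 1  # spurious detection -> (pred=1, background)


def test_confusion_column_sums_equal_gt_counts(rng):
    dets, gts, classes = random_problem(rng)
    m = confusion_matrix(dets, gts, num_classes=max(classes) + 1)
    counts = np.zeros(max(classes) + 1)
    for g in gts:
        counts[g.class_id] += 1
    assert np.array_equal(m[:, :-1].sum(axis=0), counts)


def test_confusion_class_mixup_lands_off_diagonal():
    gts = [gt("a", 0, B(0, 0, 10, 10))]
    dets = [det("a", 1, B(0, 0, 10, 10), 0.9)]  # right box, wrong class
    m = confusion_matrix(dets, gts, num_classes=2)
    assert m[1, 0] == 1 and m[0, 0] == 0
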