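"""Detection evaluation: greedy matching, precision/recall, AP/mAP and the
confusion matrix with a background class.

Protocol
--------
Detections are ranked by descending confidence.  Within an image (and, for
AP, within a class) each detection greedily claims the unmatched ground
truth with the highest IoU, provided that IoU reaches the threshold; every
ground truth can be claimed once.  AP integrates the precision envelope over
the 101-point recall grid 0, 0.01, ..., 1 (the de-facto COCO rule; the
continuous all-point rule is available behind a flag).  mAP@0.5:0.95
averages AP over IoU thresholds 0.50, 0.55, ..., 0.95.

The confusion matrix is indexed ``[predicted class, true class]`` with one
extra index for background: a missed ground truth of class ``j`` lands in
``[background, j]``; a spurious detection of class ``i`` lands in
``[i, background]``.  Columns over true classes therefore sum to the
per-class ground-truth counts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .boxloss import BoundingBox, iou

__all__ = [
    "Detection", "GroundTruth", "EvalResult",
    "match_detections", "precision_recall", "average_precision",
    "map_range", "confusion_matrix", "IOU_RANGE",
    "load_detections_yolo", "load_ground_truth_yolo",
    "write_per_class_csv", "write_confusion_csv", "plot_confusion",
]

IOU_RANGE = tuple(np.round(np.arange(0.5, 0.951, 0.05), 2))


@dataclass(frozen=True)
class Detection:
    image_id: str
    class_id: int
    box: BoundingBox
    confidence: float

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence outside [0,1]: {self.confidence}")


@dataclass(frozen=True)
class GroundTruth:
    image_id: str
    class_id: int
    box: BoundingBox


@dataclass
class EvalResult:
    """Per-class and aggregated detection quality."""

    class_ids: list
    precision: dict = field(default_factory=dict)   # class -> P at max-F1
    recall: dict = field(default_factory=dict)      # class -> R at max-F1
    ap50: dict = field(default_factory=dict)        # class -> AP@0.5
    ap: dict = field(default_factory=dict)          # class -> AP@0.5:0.95
    map50: float = 0.0
    map50_95: float = 0.0


def match_detections(dets, gts, iou_thresh: float):
    """Greedy matching on one (image, class) slice.

    Returns ``(order, tp_flags, gt_matched)``: ``order`` indexes ``dets`` by
    descending confidence, ``tp_flags[k]`` says whether ``dets[order[k]]``
    is a true positive, ``gt_matched[i]`` whether ``gts[i]`` was claimed.
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    gt_matched = [False] * len(gts)
    tp_flags = []
    for i in order:
        best, best_j = 0.0, -1
        for j, g in enumerate(gts):
            if gt_matched[j]:
                continue
            v = iou(dets[i].box, g.box)
            if v > best:
                best, best_j = v, j
        if best_j >= 0 and best >= iou_thresh:
            gt_matched[best_j] = True
            tp_flags.append(True)
        else:
            tp_flags.append(False)
    return order, tp_flags, gt_matched


def precision_recall(tp: int, fp: int, fn: int):
    """(TP/(TP+FP), TP/(TP+FN)); a zero denominator yields 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("negative counts")
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return p, r


def average_precision(flags, num_gt: int, interpolation: str = "101point") -> float:
    """AP from confidence-ranked TP/FP flags against ``num_gt`` ground truths."""
    if num_gt == 0:
        if len(flags):
            raise ValueError("no ground truth to score detections against")
        return 0.0
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        return 0.0
    tp = np.cumsum(flags)
    fp = np.cumsum(~flags)
    recall = tp / num_gt
    precision = tp / (tp + fp)
    if interpolation == "101point":
        grid = np.linspace(0.0, 1.0, 101)
        # precision envelope: best precision at recall >= r
        ap = 0.0
        for r in grid:
            mask = recall >= r - 1e-12
            ap += precision[mask].max() if mask.any() else 0.0
        return ap / 101.0
    if interpolation == "all":
        mr = np.concatenate(([0.0], recall, [1.0]))
        mp = np.concatenate(([1.0], precision, [0.0]))
        mp = np.maximum.accumulate(mp[::-1])[::-1]
        idx = np.where(mr[1:] != mr[:-1])[0]
        return float(np.sum((mr[idx + 1] - mr[idx]) * mp[idx + 1]))
    raise ValueError(f"unknown interpolation {interpolation!r}")


def _class_ranked_flags(dets, gts, cls: int, thresh: float):
    """Global confidence-ranked TP/FP flags for one class at one threshold."""
    cdets = sorted((d for d in dets if d.class_id == cls),
                   key=lambda d: -d.confidence)
    by_img: dict = {}
    for g in gts:
        if g.class_id == cls:
            by_img.setdefault(g.image_id, []).append(g)
    matched = {k: [False] * len(v) for k, v in by_img.items()}
    flags = []
    for d in cdets:
        img_gts = by_img.get(d.image_id, [])
        best, best_j = 0.0, -1
        for j, g in enumerate(img_gts):
            if matched[d.image_id][j]:
                continue
            v = iou(d.box, g.box)
            if v > best:
                best, best_j = v, j
        if best_j >= 0 and best >= thresh:
            matched[d.image_id][best_j] = True
            flags.append(True)
        else:
            flags.append(False)
    return flags, [d.confidence for d in cdets]


def map_range(dets, gts, thresholds=IOU_RANGE, class_ids=None,
              interpolation: str = "101point") -> EvalResult:
    """Per-class AP at each threshold; mAP@0.5 and the multi-threshold mean.

    Scalar precision/recall per class are taken at the confidence that
    maximizes F1 on the IoU-0.5 PR curve.
    """
    if class_ids is None:
        class_ids = sorted({g.class_id for g in gts} | {d.class_id for d in dets})
    if not class_ids:
        raise ValueError("empty class list")
    res = EvalResult(class_ids=list(class_ids))
    for cls in class_ids:
        ngt = sum(1 for g in gts if g.class_id == cls)
        aps = []
        for t in thresholds:
            flags, _ = _class_ranked_flags(dets, gts, cls, t)
            aps.append(average_precision(flags, ngt, interpolation) if ngt else 0.0)
        res.ap50[cls] = aps[0]
        res.ap[cls] = float(np.mean(aps))
        flags, _ = _class_ranked_flags(dets, gts, cls, thresholds[0])
        if ngt and flags:
            tp = np.cumsum(flags)
            fp = np.cumsum(~np.asarray(flags, dtype=bool))
            prec = tp / (tp + fp)
            rec = tp / ngt
            f1 = 2 * prec * rec / np.maximum(prec + rec, 1e-12)
            k = int(np.argmax(f1))
            res.precision[cls], res.recall[cls] = float(prec[k]), float(rec[k])
        else:
            res.precision[cls], res.recall[cls] = 0.0, 0.0
    res.map50 = float(np.mean([res.ap50[c] for c in class_ids]))
    res.map50_95 = float(np.mean([res.ap[c] for c in class_ids]))
    return res


def confusion_matrix(dets, gts, num_classes: int, conf_thresh: float = 0.25,
                     iou_thresh: float = 0.45, normalize: bool = False):
    """(m+1)x(m+1) counts indexed [predicted, true]; index m is background.

    Matching is class-agnostic (greedy on IoU) so that class confusion off
    the diagonal is visible; the normalized variant divides each true-class
    column by its sum.
    """
    m = num_classes
    mat = np.zeros((m + 1, m + 1), dtype=np.float64)
    images = {g.image_id for g in gts} | {d.image_id for d in dets}
    for img in sorted(images):
        idets = [d for d in dets if d.image_id == img and d.confidence >= conf_thresh]
        igts = [g for g in gts if g.image_id == img]
        pairs = []
        for i, d in enumerate(idets):
            for j, g in enumerate(igts):
                v = iou(d.box, g.box)
                if v >= iou_thresh:
                    pairs.append((v, i, j))
        pairs.sort(key=lambda t: -t[0])
        dused, gused = set(), set()
        for _, i, j in pairs:
            if i in dused or j in gused:
                continue
            dused.add(i)
            gused.add(j)
            mat[idets[i].class_id, igts[j].class_id] += 1
        for i, d in enumerate(idets):
            if i not in dused:
                mat[d.class_id, m] += 1
        for j, g in enumerate(igts):
            if j not in gused:
                mat[m, g.class_id] += 1
    if normalize:
        col = mat.sum(axis=0, keepdims=True)
        mat = np.divide(mat, col, out=np.zeros_like(mat), where=col > 0)
    return mat


# ------------------------------------------------------------------ I/O glue
def _parse_yolo_line(parts, image_id, with_conf):
    cls = int(float(parts[0]))
    xc, yc, w, h = map(float, parts[1:5])
    box = BoundingBox(xc, yc, w, h)
    if with_conf:
        return Detection(image_id, cls, box, float(parts[5]))
    return GroundTruth(image_id, cls, box)


def load_ground_truth_yolo(label_dir) -> list:
    """Read ``<stem>.txt`` files of ``class xc yc w h`` (normalized)."""
    out = []
    for f in sorted(Path(label_dir).glob("*.txt")):
        for line in f.read_text().splitlines():
            if line.strip():
                out.append(_parse_yolo_line(line.split(), f.stem, False))
    return out


def load_detections_yolo(label_dir) -> list:
    """Read ``class xc yc w h conf`` detection files."""
    out = []
    for f in sorted(Path(label_dir).glob("*.txt")):
        for line in f.read_text().splitlines():
            if line.strip():
                out.append(_parse_yolo_line(line.split(), f.stem, True))
    return out


def write_per_class_csv(result: EvalResult, path, class_names=None):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["class", "precision", "recall", "ap50", "ap50_95"])
        for c in result.class_ids:
            name = class_names[c] if class_names else str(c)
            w.writerow([name, f"{result.precision[c]:.6f}", f"{result.recall[c]:.6f}",
                        f"{result.ap50[c]:.6f}", f"{result.ap[c]:.6f}"])
        w.writerow(["all", "", "", f"{result.map50:.6f}", f"{result.map50_95:.6f}"])


def write_confusion_csv(mat: np.ndarray, path, class_names=None):
    m = mat.shape[0] - 1
    names = list(class_names) if class_names else [str(i) for i in range(m)]
    names = names + ["background"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["pred\\true"] + names)
        for i, row in enumerate(mat):
            w.writerow([names[i]] + [f"{v:g}" for v in row])


def plot_confusion(mat: np.ndarray, path, class_names=None):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = mat.shape[0] - 1
    names = (list(class_names) if class_names else [str(i) for i in range(m)]) + ["background"]
    fig, ax = plt.subplots(figsize=(1.0 + 0.7 * len(names), 1.0 + 0.7 * len(names)))
    ax.imshow(mat, cmap="Blues")
    ax.set_xticks(range(len(names)), names, rotation=45, ha="right")
    ax.set_yticks(range(len(names)), names)
    ax.set_xlabel("true")
    ax.set_ylabel("predicted")
    for i in range(mat.shape[0]):
        for j in range(mat.shape[1]):
            ax.text(j, i, f"{mat[i, j]:g}", ha="center", va="center", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
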