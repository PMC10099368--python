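"""Detection evaluation: IoU, NMS, matching, precision/recall, AP and mAP.

Definitions follow the standard detection-evaluation stack: precision
TP/(TP+FP), recall TP/(TP+FN), AP as the area under the interpolated
precision-recall curve of a confidence-ranked detection list, and mAP as the
unweighted mean of per-class APs — at IoU 0.5 and averaged over the ten
thresholds 0.5, 0.55, ..., 0.95.  The 0/0 convention for precision and recall
is 0.  Matching is greedy in descending confidence with single use of each
ground-truth box, per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Detection", "MatchTally", "EvalReport", "iou", "iou_matrix", "nms",
    "match_detections", "precision", "recall", "average_precision",
    "ap_from_ranked", "mean_ap", "confusion_matrix", "evaluate",
    "IOU_THRESHOLDS",
]

IOU_THRESHOLDS = np.round(np.arange(0.5, 0.96, 0.05), 2)   # 10 entries


@dataclass(frozen=True)
class Detection:
    """A predicted box in pixel xyxy with confidence and class id."""

    box: tuple[float, float, float, float]
    confidence: float
    class_id: int

    def __post_init__(self):
        x1, y1, x2, y2 = self.box
        if not (x1 < x2 and y1 < y2):
            raise ValueError("degenerate detection box")
        if not np.isfinite(self.confidence):
            raise ValueError("non-finite confidence")


@dataclass
class MatchTally:
    """TP/FP/FN bookkeeping for one class at one IoU threshold."""

    tp: int = 0
    fp: int = 0
    fn: int = 0


def precision(t: MatchTally) -> float:
    denom = t.tp + t.fp
    return t.tp / denom if denom else 0.0


def recall(t: MatchTally) -> float:
    denom = t.tp + t.fn
    return t.tp / denom if denom else 0.0


# -- geometry ----------------------------------------------------------------

def iou(a, b) -> float:
    """Intersection-over-union of two xyxy boxes."""
    return float(iou_matrix(np.asarray(a, float).reshape(1, 4),
                            np.asarray(b, float).reshape(1, 4))[0, 0])


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (n, 4) and (m, 4) xyxy boxes."""
    a = np.asarray(a, float).reshape(-1, 4)
    b = np.asarray(b, float).reshape(-1, 4)
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(br - tl, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


# -- NMS ---------------------------------------------------------------------

def nms(dets: np.ndarray, iou_thresh: float = 0.45,
        conf_thresh: float = 0.25) -> np.ndarray:
    """Class-aware greedy non-maximum suppression.

    ``dets`` is (n, 6): x1, y1, x2, y2, confidence, class.  Survivors are
    returned sorted by descending confidence; no surviving same-class pair
    overlaps above ``iou_thresh``.
    """
    dets = np.asarray(dets, float).reshape(-1, 6)
    dets = dets[dets[:, 4] >= conf_thresh]
    if not len(dets):
        return dets
    order = np.argsort(-dets[:, 4], kind="stable")
    dets = dets[order]
    keep = np.ones(len(dets), dtype=bool)
    ious = iou_matrix(dets[:, :4], dets[:, :4])
    same = dets[:, 5][:, None] == dets[:, 5][None, :]
    for i in range(len(dets)):
        if not keep[i]:
            continue
        kill = (ious[i] > iou_thresh) & same[i] & keep
        kill[: i + 1] = False
        keep &= ~kill
    return dets[keep]


# -- matching ----------------------------------------------------------------

def match_detections(dets: np.ndarray, truths: np.ndarray,
                     iou_threshold: float = 0.5,
                     num_classes: int | None = None) -> dict[int, MatchTally]:
    """Greedy confidence-descending one-to-one matching, per class.

    ``dets`` (n, 6) xyxy+conf+cls (assumed NMS-filtered), ``truths`` (m, 5)
    xyxy+cls.  Returns a tally per class; TP + FN equals the ground-truth
    count of that class.
    """
    dets = np.asarray(dets, float).reshape(-1, 6)
    truths = np.asarray(truths, float).reshape(-1, 5)
    classes = set(np.unique(truths[:, 4]).astype(int)) | \
        set(np.unique(dets[:, 5]).astype(int))
    if num_classes is not None:
        classes |= set(range(num_classes))
    tallies: dict[int, MatchTally] = {}
    for cls in sorted(classes):
        d = dets[dets[:, 5] == cls]
        t = truths[truths[:, 4] == cls]
        d = d[np.argsort(-d[:, 4], kind="stable")]
        used = np.zeros(len(t), dtype=bool)
        tp = 0
        if len(d) and len(t):
            ious = iou_matrix(d[:, :4], t[:, :4])
            for i in range(len(d)):
                cand = np.where(~used & (ious[i] >= iou_threshold))[0]
                if len(cand):
                    j = cand[np.argmax(ious[i, cand])]
                    used[j] = True
                    tp += 1
        tallies[cls] = MatchTally(tp=tp, fp=len(d) - tp, fn=len(t) - tp)
    return tallies


def _tp_flags(dets: np.ndarray, truths: np.ndarray,
              iou_threshold: float) -> np.ndarray:
    """Per-detection true-positive flags for one class on one image,
    detections already sorted by descending confidence."""
    flags = np.zeros(len(dets), dtype=bool)
    if len(dets) == 0 or len(truths) == 0:
        return flags
    used = np.zeros(len(truths), dtype=bool)
    ious = iou_matrix(dets[:, :4], truths[:, :4])
    for i in range(len(dets)):
        cand = np.where(~used & (ious[i] >= iou_threshold))[0]
        if len(cand):
            j = cand[np.argmax(ious[i, cand])]
            used[j] = True
            flags[i] = True
    return flags


# -- AP ----------------------------------------------------------------------

def ap_from_ranked(tp_flags: np.ndarray, n_truths: int,
                   mode: str = "interp101") -> float:
    """AP from confidence-ranked TP flags and the ground-truth count.

    ``interp101`` samples the precision envelope at 101 recall points
    (COCO style); ``continuous`` integrates the raw staircase with trapezoids.
    """
    tp_flags = np.asarray(tp_flags, dtype=float)
    if n_truths == 0:
        return 0.0
    if len(tp_flags) == 0 or tp_flags.sum() == 0:
        return 0.0
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(1.0 - tp_flags)
    rec = tp_cum / n_truths
    prec = tp_cum / (tp_cum + fp_cum)
    env = np.maximum.accumulate(prec[::-1])[::-1]    # precision envelope
    if mode == "interp101":
        grid = np.linspace(0, 1, 101)
        idx = np.searchsorted(rec, grid, side="left")
        q = np.where(idx < len(rec), env[np.minimum(idx, len(rec) - 1)], 0.0)
        return float(q.mean())
    if mode == "continuous":
        mrec = np.concatenate(([0.0], rec))
        return float(np.sum((mrec[1:] - mrec[:-1]) * env))
    raise ValueError(f"unknown AP mode {mode!r}")


def average_precision(dets: np.ndarray, truths: np.ndarray,
                      iou_threshold: float = 0.5,
                      mode: str = "interp101") -> float:
    """Single-class AP from (n, 5+) dets [x1 y1 x2 y2 conf ...] and (m, 4+)
    truths, both for one class (possibly pooled over images — use
    :func:`evaluate` for the per-image bookkeeping)."""
    dets = np.asarray(dets, float)
    truths = np.asarray(truths, float)
    order = np.argsort(-dets[:, 4], kind="stable") if len(dets) else []
    dets = dets[order] if len(dets) else dets.reshape(0, 5)
    flags = _tp_flags(dets, truths.reshape(-1, truths.shape[-1] if truths.size else 4),
                      iou_threshold)
    return ap_from_ranked(flags, len(truths), mode=mode)


def mean_ap(per_class_ap) -> float:
    """Unweighted mean over classes of AP (any iterable or dict of APs)."""
    vals = list(per_class_ap.values()) if isinstance(per_class_ap, dict) \
        else list(per_class_ap)
    if not vals:
        return 0.0
    return float(np.mean(vals))


# -- confusion matrix --------------------------------------------------------

def confusion_matrix(dets_per_image: list[np.ndarray],
                     truths_per_image: list[np.ndarray],
                     num_classes: int, iou_threshold: float = 0.45,
                     conf_threshold: float = 0.25) -> np.ndarray:
    """(nc+1) x (nc+1) matrix; rows = true label, columns = prediction, the
    extra index is background (missed truths / spurious detections)."""
    m = np.zeros((num_classes + 1, num_classes + 1), dtype=int)
    bg = num_classes
    for dets, truths in zip(dets_per_image, truths_per_image):
        dets = np.asarray(dets, float).reshape(-1, 6)
        dets = dets[dets[:, 4] >= conf_threshold]
        truths = np.asarray(truths, float).reshape(-1, 5)
        matched_det = np.zeros(len(dets), dtype=bool)
        matched_tr = np.zeros(len(truths), dtype=bool)
        if len(dets) and len(truths):
            ious = iou_matrix(truths[:, :4], dets[:, :4])
            order = np.argsort(-dets[:, 4], kind="stable")
            for di in order:
                cand = np.where(~matched_tr & (ious[:, di] >= iou_threshold))[0]
                if len(cand):
                    ti = cand[np.argmax(ious[cand, di])]
                    matched_tr[ti] = True
                    matched_det[di] = True
                    m[int(truths[ti, 4]), int(dets[di, 5])] += 1
        for ti in np.where(~matched_tr)[0]:
            m[int(truths[ti, 4]), bg] += 1
        for di in np.where(~matched_det)[0]:
            m[bg, int(dets[di, 5])] += 1
    return m


# -- whole-dataset evaluation -------------------------------------------------

@dataclass
class EvalReport:
    """Per-class AP, mAP@0.5, mAP@0.5:0.95, PR curves and confusion matrix."""

    per_class_ap50: dict[int, float]
    map50: float
    map50_95: float
    pr_curves: dict[int, tuple[np.ndarray, np.ndarray]]
    confusion: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_class_ap50": {int(k): float(v)
                               for k, v in self.per_class_ap50.items()},
            "map50": float(self.map50),
            "map50_95": float(self.map50_95),
            "confusion": self.confusion.tolist(),
            "class_names": list(self.class_names),
        }


def evaluate(dets_per_image: list[np.ndarray],
             truths_per_image: list[np.ndarray], num_classes: int,
             class_names: list[str] | None = None,
             mode: str = "interp101") -> EvalReport:
    """Pool detections over a dataset and produce the full report.

    Only classes with at least one ground-truth instance enter the mAP mean
    (a class absent from the data has no defined recall).
    """
    per_thr_ap: dict[float, dict[int, float]] = {}
    present = sorted({int(c) for t in truths_per_image
                      for c in np.asarray(t).reshape(-1, 5)[:, 4]})
    pr_curves: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for thr in IOU_THRESHOLDS:
        per_class: dict[int, float] = {}
        for cls in present:
            flags_all, confs, n_truth = [], [], 0
            for dets, truths in zip(dets_per_image, truths_per_image):
                dets = np.asarray(dets, float).reshape(-1, 6)
                truths = np.asarray(truths, float).reshape(-1, 5)
                d = dets[dets[:, 5] == cls]
                d = d[np.argsort(-d[:, 4], kind="stable")]
                t = truths[truths[:, 4] == cls]
                n_truth += len(t)
                flags_all.append(_tp_flags(d, t, thr))
                confs.append(d[:, 4])
            flags = np.concatenate(flags_all) if flags_all else np.zeros(0)
            confs = np.concatenate(confs) if confs else np.zeros(0)
            order = np.argsort(-confs, kind="stable")
            flags = flags[order]
            per_class[cls] = ap_from_ranked(flags, n_truth, mode=mode)
            if thr == 0.5:
                tp_cum = np.cumsum(flags.astype(float))
                fp_cum = np.cumsum(1.0 - flags.astype(float))
                rec = tp_cum / max(n_truth, 1)
                prec = tp_cum / np.maximum(tp_cum + fp_cum, 1e-12)
                pr_curves[cls] = (rec, prec)
        per_thr_ap[float(thr)] = per_class
    ap50 = per_thr_ap[0.5]
    map50 = mean_ap(ap50)
    map50_95 = float(np.mean([mean_ap(per_thr_ap[float(t)])
                              for t in IOU_THRESHOLDS]))
    conf = confusion_matrix(dets_per_image, truths_per_image, num_classes)
    return EvalReport(per_class_ap50=ap50, map50=map50, map50_95=map50_95,
                      pr_curves=pr_curves, confusion=conf,
                      class_names=class_names or [])
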