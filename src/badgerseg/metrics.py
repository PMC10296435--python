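"""Segmentation overlap/boundary metrics and one-vs-rest classification report.

Dice and Jaccard are reported on a 0-100 percent scale; the Hausdorff
distance is the true max-of-directed sup-inf Euclidean distance in pixels,
with a separate diagonal-normalized similarity score (0-100, larger better)
for summaries that want an overlap-style orientation. The two are never
conflated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import directed_hausdorff


def _as_bool(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask).astype(bool)


def _check_pair(gt: np.ndarray, se: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gt, se = _as_bool(gt), _as_bool(se)
    if gt.shape != se.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {se.shape}")
    return gt, se


def dice(gt: np.ndarray, se: np.ndarray) -> float:
    """Dice similarity 2|GT & SE| / (|GT| + |SE|), in percent.

    Two empty masks are identical by convention and score 100.
    """
    gt, se = _check_pair(gt, se)
    denom = gt.sum() + se.sum()
    if denom == 0:
        return 100.0
    return 200.0 * np.logical_and(gt, se).sum() / denom


def jaccard(gt: np.ndarray, se: np.ndarray) -> float:
    """Jaccard overlap |GT & SE| / |GT | SE|, in percent (100 if both empty)."""
    gt, se = _check_pair(gt, se)
    union = np.logical_or(gt, se).sum()
    if union == 0:
        return 100.0
    return 100.0 * np.logical_and(gt, se).sum() / union


def hausdorff(gt: np.ndarray, se: np.ndarray) -> float:
    """Symmetric Hausdorff distance between foreground point sets, in pixels."""
    gt, se = _check_pair(gt, se)
    if not gt.any() or not se.any():
        raise ValueError("Hausdorff distance needs non-empty masks")
    a = np.argwhere(gt).astype(float)
    b = np.argwhere(se).astype(float)
    return max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])


def hausdorff_score(gt: np.ndarray, se: np.ndarray) -> float:
    """Diagonal-normalized Hausdorff similarity 100*(1 - HD/diag), clipped to [0, 100]."""
    gt, se = _check_pair(gt, se)
    hd = hausdorff(gt, se)
    diag = float(np.hypot(*gt.shape))
    return float(np.clip(100.0 * (1.0 - hd / diag), 0.0, 100.0))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _safe(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return 100.0 * num / den, False


def class_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall and F1 (percent) from one-vs-rest counts."""
    acc, _ = _safe(c.tp + c.tn, c.n)
    prec, prec_flag = _safe(c.tp, c.tp + c.fp)
    rec, rec_flag = _safe(c.tp, c.tp + c.fn)
    f1, f1_flag = _safe(2 * c.tp, 2 * c.tp + c.fp + c.fn)
    return {
        "accuracy": acc,
        "precision": prec,
        "recall": rec,
        "f1": f1,
        "undefined": bool(prec_flag or rec_flag or f1_flag),
    }


def classification_report(y_true, y_pred, classes=None) -> dict:
    """Per-class one-vs-rest metrics plus unweighted (macro) averages.

    Returns a dict with ``per_class`` (counts + metrics per class label),
    ``macro`` (mean accuracy/precision/recall/F1 over classes) and
    ``overall_accuracy`` (plain fraction of correct predictions, percent).
    Zero-denominator metrics are reported as 0 and flagged.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if classes is None:
        classes = sorted(np.unique(np.concatenate([y_true, y_pred])).tolist())
    unknown = set(np.unique(np.concatenate([y_true, y_pred]))) - set(classes)
    if unknown:
        raise ValueError(f"labels outside the class set: {unknown}")
    per_class = {}
    for c in classes:
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        tn = int(np.sum((y_true != c) & (y_pred != c)))
        counts = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
        m = class_metrics(counts)
        per_class[str(c)] = {"tp": tp, "tn": tn, "fp": fp, "fn": fn, **m}
    macro = {
        key: float(np.mean([per_class[str(c)][key] for c in classes]))
        for key in ("accuracy", "precision", "recall", "f1")
    }
    overall = 100.0 * float(np.mean(y_true == y_pred))
    return {"per_class": per_class, "macro": macro, "overall_accuracy": overall}


def match_segments(gt_labels: np.ndarray, pred_labels: np.ndarray) -> dict[int, int]:
    """Greedy best-overlap matching of predicted segments to ground-truth labels.

    Pairs (gt, pred) are matched in decreasing order of intersection size,
    each side used at most once. Used to score k-way masks whose label ids
    carry no meaning.
    """
    gt_labels = np.asarray(gt_labels)
    pred_labels = np.asarray(pred_labels)
    gts = np.unique(gt_labels)
    preds = np.unique(pred_labels)
    overlaps = []
    for g in gts:
        gm = gt_labels == g
        for p in preds:
            overlaps.append((int(np.sum(gm & (pred_labels == p))), int(g), int(p)))
    overlaps.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_g, used_p, match = set(), set(), {}
    for ov, g, p in overlaps:
        if g in used_g or p in used_p:
            continue
        match[g] = p
        used_g.add(g)
        used_p.add(p)
    return match


def segmentation_scores(gt_labels: np.ndarray, pred_labels: np.ndarray) -> dict:
    """Mean per-region Dice/Jaccard (and HD similarity) after label matching.

    Ground-truth label 0 is treated as background and excluded from the
    averages; regions left unmatched score 0 overlap.
    """
    match = match_segments(gt_labels, pred_labels)
    dscs, jcs, hds = [], [], []
    for g in np.unique(gt_labels):
        if g == 0:
            continue
        gm = gt_labels == g
        if g in match:
            pm = pred_labels == match[g]
            dscs.append(dice(gm, pm))
            jcs.append(jaccard(gm, pm))
            hds.append(hausdorff_score(gm, pm) if pm.any() else 0.0)
        else:
            dscs.append(0.0)
            jcs.append(0.0)
            hds.append(0.0)
    return {
        "dice": float(np.mean(dscs)),
        "jaccard": float(np.mean(jcs)),
        "hausdorff_score": float(np.mean(hds)),
        "per_region_dice": dscs,
    }
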