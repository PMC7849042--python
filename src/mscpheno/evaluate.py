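"""Evaluation of detection, segmentation and classification against truth.

Detection errors follow a five-way taxonomy: TP (correct detections), FN1
(missed cells in truth regions the algorithm found nothing in), FN2
(under-detection — too few cells found inside a truth cluster), FP1 (objects
detected where no truth cell exists) and FP2 (over-detection — surplus objects
inside a truth cluster). Sensitivity is TP/(TP+FN1+FN2), precision is
TP/(TP+FP1+FP2), and per-cell overlap is the Sorensen-Dice coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

_STRUCT8 = np.ones((3, 3), dtype=bool)

APS_CATEGORIES = (
    "highly_RS",
    "moderately_RS",
    "uncertain",
    "moderately_SR",
    "highly_SR",
)


@dataclass
class DetectionCounts:
    TP: int = 0
    FN1: int = 0
    FN2: int = 0
    FP1: int = 0
    FP2: int = 0

    def __post_init__(self) -> None:
        for name in ("TP", "FN1", "FN2", "FP1", "FP2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def __add__(self, other: "DetectionCounts") -> "DetectionCounts":
        return DetectionCounts(
            TP=self.TP + other.TP,
            FN1=self.FN1 + other.FN1,
            FN2=self.FN2 + other.FN2,
            FP1=self.FP1 + other.FP1,
            FP2=self.FP2 + other.FP2,
        )


def sensitivity(c: DetectionCounts) -> float:
    """TP / (TP + FN1 + FN2); NaN when no truth cells."""
    denom = c.TP + c.FN1 + c.FN2
    return c.TP / denom if denom > 0 else float("nan")


def precision(c: DetectionCounts) -> float:
    """TP / (TP + FP1 + FP2); NaN when nothing was detected."""
    denom = c.TP + c.FP1 + c.FP2
    return c.TP / denom if denom > 0 else float("nan")


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Sorensen-Dice overlap 2|A∩B| / (|A|+|B|); NaN when both are empty."""
    if mask_a.shape != mask_b.shape:
        raise ValueError("mask shapes differ")
    a = np.count_nonzero(mask_a)
    b = np.count_nonzero(mask_b)
    if a + b == 0:
        return float("nan")
    inter = np.count_nonzero(mask_a & mask_b)
    return 2.0 * inter / (a + b)


def _truth_clusters(truth: np.ndarray, regions: np.ndarray | None) -> dict[int, int]:
    """Map each truth label to a cluster id.

    Clusters are truth cells sharing a connected component — of the supplied
    candidate-region mask when given, otherwise of the truth foreground
    itself (fixture clusters touch by construction).
    """
    if regions is None:
        comp, _ = ndimage.label(truth > 0, structure=_STRUCT8)
    else:
        comp, _ = ndimage.label(regions > 0, structure=_STRUCT8)
    out: dict[int, int] = {}
    next_orphan = comp.max() + 1
    for t in np.unique(truth):
        if t == 0:
            continue
        vals, counts = np.unique(comp[truth == t], return_counts=True)
        nz = vals[vals > 0]
        if nz.size:
            out[int(t)] = int(nz[np.argmax(counts[vals > 0])])
        else:
            out[int(t)] = next_orphan  # truth cell missed by the region mask
            next_orphan += 1
    return out


def match_pairs(
    pred: np.ndarray, truth: np.ndarray, min_overlap_frac: float = 0.5
) -> list[tuple[int, int, int]]:
    """Maximal-overlap one-to-one matching.

    A (truth, pred) pair is valid when their intersection exceeds
    ``min_overlap_frac`` of the truth cell's area; pairs are accepted greedily
    by descending overlap (ties: lower labels), each label used at most once.
    Returns (truth_label, pred_label, overlap_px) triples.
    """
    truth_ids = [int(t) for t in np.unique(truth) if t != 0]
    truth_areas = {t: int(np.count_nonzero(truth == t)) for t in truth_ids}
    overlaps: list[tuple[int, int, int]] = []
    for t in truth_ids:
        vals, counts = np.unique(pred[truth == t], return_counts=True)
        for v, c in zip(vals, counts):
            if v != 0 and c > min_overlap_frac * truth_areas[t]:
                overlaps.append((t, int(v), int(c)))
    overlaps.sort(key=lambda x: (-x[2], x[0], x[1]))
    used_t: set[int] = set()
    used_p: set[int] = set()
    pairs = []
    for t, v, c in overlaps:
        if t in used_t or v in used_p:
            continue
        pairs.append((t, v, c))
        used_t.add(t)
        used_p.add(v)
    return pairs


def match_detections(
    pred: np.ndarray,
    truth: np.ndarray,
    regions: np.ndarray | None = None,
    min_overlap_frac: float = 0.5,
) -> DetectionCounts:
    """Count TP/FN1/FN2/FP1/FP2 for one image.

    Unmatched truth cells in clusters where the algorithm found nothing are
    missed detections (FN1); unmatched truth cells in clusters with at least
    one detection are under-detections (FN2). Unmatched predictions that
    overlap no truth cluster are false detections (FP1); surplus predictions
    inside a truth cluster are over-detections (FP2).
    """
    if pred.shape != truth.shape:
        raise ValueError("label map shapes differ")
    pairs = match_pairs(pred, truth, min_overlap_frac)
    matched_t = {t for t, _, _ in pairs}
    matched_p = {p for _, p, _ in pairs}
    clusters = _truth_clusters(truth, regions)
    cluster_of_truth = clusters
    # assign each prediction to the truth cluster it overlaps most (0 = none)
    pred_ids = [int(p) for p in np.unique(pred) if p != 0]
    truth_cluster_raster = np.zeros_like(truth)
    for t, c in clusters.items():
        truth_cluster_raster[truth == t] = c
    pred_cluster: dict[int, int] = {}
    for p in pred_ids:
        vals, counts = np.unique(truth_cluster_raster[pred == p], return_counts=True)
        nz = vals > 0
        pred_cluster[p] = int(vals[nz][np.argmax(counts[nz])]) if nz.any() else 0
    counts = DetectionCounts(TP=len(pairs))
    fn1 = fn2 = fp1 = fp2 = 0
    cluster_ids = set(cluster_of_truth.values())
    preds_per_cluster: dict[int, int] = {c: 0 for c in cluster_ids}
    for p, c in pred_cluster.items():
        if c == 0:
            if p not in matched_p:
                fp1 += 1
        else:
            preds_per_cluster[c] = preds_per_cluster.get(c, 0) + 1
    for c in cluster_ids:
        truths = [t for t, cc in cluster_of_truth.items() if cc == c]
        unmatched = [t for t in truths if t not in matched_t]
        n_pred = preds_per_cluster.get(c, 0)
        if n_pred == 0:
            fn1 += len(unmatched)
        else:
            fn2 += len(unmatched)
        matched_here = len([t for t in truths if t in matched_t])
        surplus = n_pred - matched_here
        if surplus > 0:
            fp2 += surplus
    return DetectionCounts(TP=len(pairs), FN1=fn1, FN2=fn2, FP1=fp1, FP2=fp2)


def per_cell_dice(pred: np.ndarray, truth: np.ndarray, min_overlap_frac: float = 0.5) -> pd.DataFrame:
    """Per truth-cell Dice against its matched prediction (0 when unmatched)."""
    pairs = {t: p for t, p, _ in match_pairs(pred, truth, min_overlap_frac)}
    rows = []
    for t in sorted(set(np.unique(truth)) - {0}):
        p = pairs.get(int(t))
        d = dice(truth == t, pred == p) if p is not None else 0.0
        rows.append({"truth_id": int(t), "pred_id": p, "dice": d, "matched": p is not None})
    return pd.DataFrame(rows)


def per_image_summary(
    images: list[tuple[np.ndarray, np.ndarray]],
    regions: list[np.ndarray] | None = None,
    min_overlap_frac: float = 0.5,
) -> dict:
    """Per-image sensitivity, precision and mean cell Dice, plus dataset-level
    mean +/- sample SD of each; Dice aggregates are reported both over all
    truth cells and over correctly detected (matched) cells only."""
    if not images:
        raise ValueError("at least one (pred, truth) image pair required")
    per_image = []
    all_dice: list[float] = []
    tp_dice: list[float] = []
    for i, (pred, truth) in enumerate(images):
        reg = regions[i] if regions else None
        c = match_detections(pred, truth, reg, min_overlap_frac)
        dd = per_cell_dice(pred, truth, min_overlap_frac)
        all_dice.extend(dd["dice"].tolist())
        tp_dice.extend(dd.loc[dd["matched"], "dice"].tolist())
        per_image.append(
            {
                "image": i,
                "sensitivity": sensitivity(c),
                "precision": precision(c),
                "mean_dice": float(dd["dice"].mean()) if len(dd) else float("nan"),
                **{k: getattr(c, k) for k in ("TP", "FN1", "FN2", "FP1", "FP2")},
            }
        )
    df = pd.DataFrame(per_image)

    def _ms(x: pd.Series | list[float]) -> tuple[float, float]:
        arr = np.asarray(x, dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size == 0:
            return float("nan"), float("nan")
        sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
        return float(arr.mean()), sd

    s_mean, s_sd = _ms(df["sensitivity"])
    p_mean, p_sd = _ms(df["precision"])
    d_mean, d_sd = _ms(df["mean_dice"])
    all_mean, all_sd = _ms(all_dice)
    tp_mean, tp_sd = _ms(tp_dice)
    return {
        "per_image": df,
        "sensitivity_mean": s_mean,
        "sensitivity_sd": s_sd,
        "precision_mean": p_mean,
        "precision_sd": p_sd,
        "dice_mean": d_mean,
        "dice_sd": d_sd,
        "dice_all_cells": (all_mean, all_sd),
        "dice_tp_cells": (tp_mean, tp_sd),
    }


def aps_category(observer_labels: list[int] | np.ndarray) -> tuple[float, str]:
    """Average phenotype score (mean of binary RS=0/SR=1 observer labels) and
    its confidence category.

    Boundaries: <=0.15 highly RS; (0.15, 0.40) moderately RS; [0.40, 0.60]
    uncertain; (0.60, 0.85) moderately SR; >=0.85 highly SR.
    """
    labels = np.asarray(observer_labels, dtype=float)
    if labels.size == 0:
        raise ValueError("at least one observer label required")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("observer labels must be binary RS=0 / SR=1")
    aps = float(labels.mean())
    if aps <= 0.15:
        cat = "highly_RS"
    elif aps < 0.40:
        cat = "moderately_RS"
    elif aps <= 0.60:
        cat = "uncertain"
    elif aps < 0.85:
        cat = "moderately_SR"
    else:
        cat = "highly_SR"
    return aps, cat
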