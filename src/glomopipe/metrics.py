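"""Quantification of sclerosis and the evaluation layer.

Per glomerulus, the clinically relevant summary is the sclerotic
proportion: sclerotic area over the *whole glomerular tuft* (tuft +
sclerotic areas combined).  A globally sclerosed glomerulus with no
remaining tuft scores 1 by this formula; a crop with neither tuft nor
sclerosis has no defined proportion and is excluded from slide-level
means.

The evaluation layer provides per-class and mean IoU over the five-class
scheme, fold aggregation as mean (standard error), Welch's t-test for
comparing two groups of fold metrics, and the Pearson correlation between
ground-truth and predicted per-slide region totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError, UndefinedResultError
from .wsi import CLASS_NAMES, N_CLASSES, LabelMask

__all__ = [
    "GlomQuant",
    "quantify_glomeruli",
    "wsi_sclerotic_proportion",
    "iou_per_class",
    "confusion_counts",
    "iou_from_confusion",
    "fold_iou",
    "mean_iou",
    "aggregate_folds",
    "welch_t_test",
    "truth_pred_correlation",
]


@dataclass(frozen=True)
class GlomQuant:
    """Per-glomerulus class areas (μm²) and sclerotic proportion."""

    glom_id: int
    area_bowman: float
    area_tuft: float
    area_crescent: float
    area_sclerotic: float

    @property
    def whole_tuft_area(self) -> float:
        """Whole glomerular tuft = tuft + sclerotic regions combined."""
        return self.area_tuft + self.area_sclerotic

    @property
    def sclerotic_proportion(self) -> float:
        """Sclerotic / whole tuft; NaN when there is no tuft tissue at all."""
        wt = self.whole_tuft_area
        return self.area_sclerotic / wt if wt > 0 else float("nan")


def quantify_glomeruli(per_glom_masks: Sequence[LabelMask],
                       glom_ids: Sequence[int] | None = None) -> list[GlomQuant]:
    """Class areas and sclerotic proportion for each per-glomerulus mask."""
    ids = list(glom_ids) if glom_ids is not None else list(range(len(per_glom_masks)))
    out = []
    for gid, mask in zip(ids, per_glom_masks):
        areas = mask.class_areas_um2()
        out.append(
            GlomQuant(
                glom_id=gid,
                area_bowman=float(areas[1]),
                area_tuft=float(areas[2]),
                area_crescent=float(areas[3]),
                area_sclerotic=float(areas[4]),
            )
        )
    return out


def quants_to_frame(quants: Sequence[GlomQuant], wsi_id: str = "wsi") -> pd.DataFrame:
    rows = [
        {
            "wsi_id": wsi_id,
            "glom_id": q.glom_id,
            "area_bowman": q.area_bowman,
            "area_tuft": q.area_tuft,
            "area_crescent": q.area_crescent,
            "area_sclerotic": q.area_sclerotic,
            "sclerotic_prop": q.sclerotic_proportion,
        }
        for q in quants
    ]
    return pd.DataFrame(rows)


def wsi_sclerotic_proportion(quants: Sequence[GlomQuant], mode: str = "mean_of_gloms") -> float:
    """Slide-level sclerotic proportion.

    `mean_of_gloms` (default) averages the defined per-glomerulus
    proportions without area weighting; `pooled_areas` is total sclerotic
    over total whole-tuft area.  Glomeruli with no tuft tissue are excluded
    from the mean.
    """
    if mode == "mean_of_gloms":
        props = [q.sclerotic_proportion for q in quants if q.whole_tuft_area > 0]
        if not props:
            raise UndefinedResultError("no glomerulus with a defined sclerotic proportion")
        return float(np.mean(props))
    if mode == "pooled_areas":
        wt = sum(q.whole_tuft_area for q in quants)
        if wt <= 0:
            raise UndefinedResultError("zero total whole-tuft area")
        return float(sum(q.area_sclerotic for q in quants) / wt)
    raise InvalidInputError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# IoU evaluation


def confusion_counts(pred: LabelMask | np.ndarray, truth: LabelMask | np.ndarray) -> np.ndarray:
    """5×5 confusion matrix of pixel counts, truth on rows, prediction on columns."""
    p = pred.data if isinstance(pred, LabelMask) else np.asarray(pred)
    t = truth.data if isinstance(truth, LabelMask) else np.asarray(truth)
    if p.shape != t.shape:
        raise InvalidInputError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    flat = t.astype(np.int64).ravel() * N_CLASSES + p.astype(np.int64).ravel()
    return np.bincount(flat, minlength=N_CLASSES * N_CLASSES).reshape(N_CLASSES, N_CLASSES)


def iou_from_confusion(conf: np.ndarray) -> np.ndarray:
    """Per-class IoU from a confusion matrix; NaN for classes absent from both."""
    inter = np.diag(conf).astype(float)
    union = conf.sum(axis=0) + conf.sum(axis=1) - np.diag(conf)
    with np.errstate(invalid="ignore"):
        iou = np.where(union > 0, inter / np.maximum(union, 1), np.nan)
    return iou


def iou_per_class(pred: LabelMask | np.ndarray, truth: LabelMask | np.ndarray) -> np.ndarray:
    """Per-class IoU vector (length 5); classes absent from both sides are NaN."""
    return iou_from_confusion(confusion_counts(pred, truth))


def mean_iou(iou: np.ndarray) -> float:
    """Unweighted mean of the defined per-class IoUs."""
    return float(np.nanmean(iou))


def fold_iou(pairs: Sequence[tuple]) -> np.ndarray:
    """Micro-averaged per-class IoU for one fold: pixel counts pooled over images."""
    conf = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    for pred, truth in pairs:
        conf += confusion_counts(pred, truth)
    return iou_from_confusion(conf)


def aggregate_folds(values: Sequence) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Mean and standard error (sample SD / √k) across folds.

    Accepts scalars or per-class vectors; with a single fold the SE is NaN.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.shape[0] == 0:
        raise UndefinedResultError("no folds")
    mean = np.nanmean(arr, axis=0)
    if arr.shape[0] < 2:
        se = np.full_like(np.atleast_1d(mean), np.nan, dtype=float)
        se = se if np.ndim(mean) else float(se[0])
    else:
        se = np.nanstd(arr, axis=0, ddof=1) / np.sqrt(arr.shape[0])
    return (float(mean), float(se)) if np.ndim(mean) == 0 else (mean, se)


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's t-test for the equality of two means: (t, df, two-sided p).

    Uses the Welch–Satterthwaite degrees of freedom; requires both samples
    of size ≥ 2 with positive variance in at least one.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise UndefinedResultError("Welch's t-test needs ≥ 2 observations per sample")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise UndefinedResultError("both samples are constant; Welch statistic undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def truth_pred_correlation(truth_totals: Sequence[float],
                           pred_totals: Sequence[float]) -> float:
    """Pearson r between ground-truth and predicted per-slide region totals."""
    t = np.asarray(truth_totals, dtype=float)
    p = np.asarray(pred_totals, dtype=float)
    if t.size != p.size or t.size < 3:
        raise UndefinedResultError("need ≥ 3 paired totals")
    if t.std() == 0 or p.std() == 0:
        raise UndefinedResultError("zero variance in one of the series")
    return float(stats.pearsonr(t, p).statistic)


def iou_report_frame(per_fold_ious: Sequence[np.ndarray], label: str = "") -> pd.DataFrame:
    """Table-shaped report: one row, per-class + mean columns of "mean (SE)" cells."""
    mean, se = aggregate_folds(per_fold_ious)
    mi, mi_se = aggregate_folds([mean_iou(v) for v in per_fold_ious])
    cells = {
        CLASS_NAMES[c]: f"{mean[c]:.3f} ({se[c]:.3f})" for c in range(N_CLASSES)
    }
    cells["mean_iou"] = f"{mi:.3f} ({mi_se:.3f})"
    return pd.DataFrame([cells], index=[label or "model"])
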