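"""Detection scoring: confusion counts, classification metrics, AUC, HRV.

Two evaluation paths share the same confusion-count container: window-level
classification (labels known per ROI) and end-to-end location matching of
detected against annotated R samples within a tolerance (150 ms by default,
the conventional QRS-matching window).

The six classification metrics follow the printed forms, including the
nonstandard ones: DER = (FP+FN)/TP, Accuracy = TP/(TP+FP+FN) and
Recall = TP/(TP+TN). Percentages are rounded half-up to two decimals only
at the reporting layer.

The three heart-rate-variability statistics are computed over the R-R
interval series (seconds): MRR is the mean of the N−1 intervals, SDNN the
root mean square deviation of the intervals from MRR (divisor N−1 = the
interval count), and RMSSD the root mean square of the N−2 successive
interval differences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "HRVReport",
    "match_detections",
    "classification_metrics",
    "hrv_metrics",
    "aggregate_hrv",
    "auc",
    "round_half_up",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")


def round_half_up(x: float, ndigits: int = 2) -> float:
    if not math.isfinite(x):
        return x
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -ndigits, rounding=ROUND_HALF_UP))


@dataclass
class MetricsReport:
    """Percentages, full precision; use :meth:`rounded` for the 2-decimal view."""

    sensitivity: float
    specificity: float
    precision: float
    recall: float
    der: float
    accuracy: float

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        return {k: round_half_up(v, ndigits) for k, v in vars(self).items()}


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def classification_metrics(c: ConfusionCounts) -> MetricsReport:
    """The six metrics, as percentages at full precision."""
    return MetricsReport(
        sensitivity=100.0 * _ratio(c.tp, c.tp + c.fn, "sensitivity"),
        specificity=100.0 * _ratio(c.tn, c.tn + c.fp, "specificity"),
        precision=100.0 * _ratio(c.tp, c.tp + c.fp, "precision"),
        recall=100.0 * _ratio(c.tp, c.tp + c.tn, "recall"),
        der=100.0 * _ratio(c.fp + c.fn, c.tp, "DER"),
        accuracy=100.0 * _ratio(c.tp, c.tp + c.fp + c.fn, "accuracy"),
    )


def match_detections(
    detected,
    annotated,
    fs: float,
    tolerance_s: float = 0.15,
) -> ConfusionCounts:
    """Greedy one-to-one nearest matching of detections to annotations.

    Candidate pairs within round(tolerance_s·fs) samples are accepted
    closest-first, each detection and each annotation matching at most once.
    Matched pairs are TP, unmatched detections FP, unmatched annotations FN;
    TN is not defined for location matching and reported as 0. Both input
    lists must be sorted; the result is invariant to a common time shift.
    """
    det = np.asarray(detected, dtype=int)
    ann = np.asarray(annotated, dtype=int)
    tol = int(round(tolerance_s * fs))
    pairs = []
    j0 = 0
    for i, d in enumerate(det):
        while j0 < ann.size and ann[j0] < d - tol:
            j0 += 1
        j = j0
        while j < ann.size and ann[j] <= d + tol:
            pairs.append((abs(int(d) - int(ann[j])), i, j))
            j += 1
    pairs.sort()
    det_used = np.zeros(det.size, dtype=bool)
    ann_used = np.zeros(ann.size, dtype=bool)
    tp = 0
    for _, i, j in pairs:
        if not det_used[i] and not ann_used[j]:
            det_used[i] = ann_used[j] = True
            tp += 1
    return ConfusionCounts(tp=tp, fp=int(det.size - tp), tn=0, fn=int(ann.size - tp))


@dataclass
class HRVReport:
    mrr: float    # s
    sdnn: float   # s
    rmssd: float  # s


def hrv_metrics(r_locations, fs: float) -> HRVReport:
    """MRR/SDNN/RMSSD of the R-R interval series, in seconds.

    Needs >= 2 R locations for MRR/SDNN and >= 3 for RMSSD; missing
    quantities are NaN.
    """
    locs = np.asarray(r_locations, dtype=float)
    if locs.size < 2:
        warnings.warn("HRV undefined with fewer than 2 R peaks", RuntimeWarning, stacklevel=2)
        return HRVReport(float("nan"), float("nan"), float("nan"))
    rr = np.diff(locs) / fs
    mrr = float(rr.mean())
    sdnn = float(np.sqrt(np.mean((rr - mrr) ** 2)))
    if rr.size >= 2:
        rmssd = float(np.sqrt(np.mean(np.diff(rr) ** 2)))
    else:
        rmssd = float("nan")
    return HRVReport(mrr=mrr, sdnn=sdnn, rmssd=rmssd)


def aggregate_hrv(location_lists, fs: float, mode: str = "pooled") -> HRVReport:
    """HRV across several records.

    ``pooled`` computes the statistics over the union of all records' R-R
    intervals (successive differences never cross record boundaries);
    ``per-record`` averages the per-record HRV reports. Which convention a
    published multi-record HRV figure uses is often unstated, so both are
    offered.
    """
    if mode == "per-record":
        reports = [hrv_metrics(locs, fs) for locs in location_lists if len(locs) >= 3]
        if not reports:
            return HRVReport(float("nan"), float("nan"), float("nan"))
        return HRVReport(
            mrr=float(np.mean([r.mrr for r in reports])),
            sdnn=float(np.mean([r.sdnn for r in reports])),
            rmssd=float(np.mean([r.rmssd for r in reports])),
        )
    if mode != "pooled":
        raise ValueError(f"unknown HRV aggregation mode {mode!r}")
    rrs = [np.diff(np.asarray(locs, dtype=float)) / fs for locs in location_lists if len(locs) >= 2]
    if not rrs:
        return HRVReport(float("nan"), float("nan"), float("nan"))
    pooled = np.concatenate(rrs)
    mrr = float(pooled.mean())
    sdnn = float(np.sqrt(np.mean((pooled - mrr) ** 2)))
    sq_diffs = [np.diff(rr) ** 2 for rr in rrs if rr.size >= 2]
    rmssd = float(np.sqrt(np.mean(np.concatenate(sq_diffs)))) if sq_diffs else float("nan")
    return HRVReport(mrr=mrr, sdnn=sdnn, rmssd=rmssd)


def auc(scores, labels) -> float:
    """Rank-based area under the ROC curve of vote fractions vs. labels."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        warnings.warn("AUC undefined with a single class", RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))
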