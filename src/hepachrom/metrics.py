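"""Validation statistics for the analyzer.

Method agreement against a commercial analyzer (Pearson r, % variation,
CLIA total-allowable-error check), regression error (MAE/RMSE/R^2),
one-vs-rest classification metrics on the five clinical categories
(confusion matrix, accuracy/sensitivity/specificity, ROC AUC), precision
(%CV of replicate series), blank-based limit of detection, and the
over-range dilution prompt.

Conventions: sample (n-1) standard deviations throughout; unweighted macro
averages across the five categories (classes are balanced by construction);
% variation uses the commercial reading as denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    confusion_matrix as _sk_confusion,
    mean_absolute_error,
    mean_squared_error,
    r2_score,
    roc_auc_score,
)

from .assays import AssayDefinition
from .dataset import CategoryScheme

__all__ = [
    "PairedMeasurements",
    "ConfusionCounts",
    "RegressionMetrics",
    "ClassMetrics",
    "ReplicateSeries",
    "DilutionAdvice",
    "pearson_r",
    "percent_variation",
    "clia_check",
    "regression_metrics",
    "confusion_matrix",
    "class_counts",
    "class_metrics",
    "macro_class_metrics",
    "roc_auc",
    "macro_ovr_auc",
    "category_scores",
    "cv_percent",
    "limit_of_detection",
    "dilution_advice",
    "corrected_after_dilution",
    "agreement_report",
]


@dataclass(frozen=True)
class PairedMeasurements:
    """Matched readings: x from the commercial analyzer, y from the
    developed platform."""

    x: Tuple[float, ...]
    y: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y):
            raise ValueError("x and y must have equal length")
        if len(self.x) < 2:
            raise ValueError("need at least 2 paired measurements")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("measurements must be finite")


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest counts for a single class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class RegressionMetrics:
    mae: float
    rmse: float
    r2: float


@dataclass(frozen=True)
class ClassMetrics:
    accuracy: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class ReplicateSeries:
    """Repeated measurements of one sample in one repeatability context
    (same-day / different-day / different-user)."""

    values: Tuple[float, ...]
    context: str = "same-day"

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise ValueError("a replicate series needs at least 2 values")


@dataclass(frozen=True)
class DilutionAdvice:
    needs_dilution: bool
    factor: int
    message: str = ""


def pearson_r(pairs: PairedMeasurements) -> float:
    """Product-moment correlation between the two analyzers' readings."""
    x = np.asarray(pairs.x)
    y = np.asarray(pairs.y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant sequence")
    return float(stats.pearsonr(x, y).statistic)


def percent_variation(x: float, y: float) -> float:
    """Absolute relative difference, in %, with the commercial reading x as
    denominator: ``100 * |y - x| / x``."""
    if x == 0:
        raise ValueError("percent variation undefined for x = 0")
    return 100.0 * abs(y - x) / abs(x)


def clia_check(x: float, y: float, tea_percent: float = 10.0) -> bool:
    """Total-allowable-error check: deviation within +/- tea_percent of the
    target concentration (boundary inclusive)."""
    if x <= 0:
        raise ValueError("target concentration must be positive")
    return percent_variation(x, y) <= tea_percent


def regression_metrics(true: Sequence[float], pred: Sequence[float]) -> RegressionMetrics:
    """MAE, RMSE and R^2 of predicted vs true concentrations."""
    t = np.asarray(true, dtype=np.float64)
    p = np.asarray(pred, dtype=np.float64)
    if t.shape != p.shape or t.size == 0:
        raise ValueError("true and pred must be equal-length and nonempty")
    if np.ptp(t) == 0:
        raise ValueError("R^2 undefined for a constant true sequence")
    return RegressionMetrics(
        mae=float(mean_absolute_error(t, p)),
        rmse=float(np.sqrt(mean_squared_error(t, p))),
        r2=float(r2_score(t, p)),
    )


def confusion_matrix(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    scheme: CategoryScheme,
) -> pd.DataFrame:
    """5x5 count matrix; rows are true categories, columns predicted."""
    names = list(scheme.names)
    for lbl in list(true_labels) + list(predicted_labels):
        if lbl not in names:
            raise ValueError(f"unknown category label {lbl!r}")
    mat = _sk_confusion(true_labels, predicted_labels, labels=names)
    return pd.DataFrame(mat, index=names, columns=names)


def class_counts(matrix: pd.DataFrame, cls: str) -> ConfusionCounts:
    """Collapse the 5x5 matrix into one-vs-rest counts for ``cls``."""
    if cls not in matrix.index:
        raise ValueError(f"unknown class {cls!r}")
    total = int(matrix.values.sum())
    tp = int(matrix.loc[cls, cls])
    fn = int(matrix.loc[cls].sum()) - tp
    fp = int(matrix[cls].sum()) - tp
    return ConfusionCounts(tp=tp, tn=total - tp - fn - fp, fp=fp, fn=fn)


def class_metrics(matrix: pd.DataFrame, cls: str) -> ClassMetrics:
    """Accuracy, sensitivity and specificity for one class (one-vs-rest).

    accuracy = (TP+TN)/(TP+TN+FP+FN); sensitivity = TP/(TP+FN);
    specificity = TN/(TN+FP). A zero denominator yields NaN for that ratio.
    """
    c = class_counts(matrix, cls)
    if c.total == 0:
        raise ValueError("empty confusion matrix")

    def _ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    return ClassMetrics(
        accuracy=_ratio(c.tp + c.tn, c.total),
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
    )


def macro_class_metrics(matrix: pd.DataFrame) -> ClassMetrics:
    """Unweighted macro average across classes; undefined (NaN) per-class
    ratios are excluded from their average."""
    per = [class_metrics(matrix, cls) for cls in matrix.index]

    def _mean(vals: List[float]) -> float:
        ok = [v for v in vals if np.isfinite(v)]
        return float(np.mean(ok)) if ok else float("nan")

    return ClassMetrics(
        accuracy=_mean([m.accuracy for m in per]),
        sensitivity=_mean([m.sensitivity for m in per]),
        specificity=_mean([m.specificity for m in per]),
    )


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Trapezoidal area under the ROC curve of a continuous score."""
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("ROC AUC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=np.float64)))


def category_scores(
    predictions: Sequence[float], scheme: CategoryScheme
) -> np.ndarray:
    """(N, 5) continuous class scores for binned regression outputs.

    Score of class k is the negative absolute distance from the predicted
    concentration to bin k's midpoint: monotone, continuous and
    threshold-sweepable.
    """
    pred = np.asarray(predictions, dtype=np.float64)[:, None]
    return -np.abs(pred - scheme.midpoints()[None, :])


def macro_ovr_auc(
    predictions: Sequence[float],
    true_labels: Sequence[str],
    scheme: CategoryScheme,
) -> float:
    """Macro one-vs-rest AUC over the five categories.

    Classes absent from ``true_labels`` (or covering all of them) have no
    defined AUC and are excluded from the average.
    """
    scores = category_scores(predictions, scheme)
    true = np.asarray(true_labels)
    aucs = []
    for k, name in enumerate(scheme.names):
        y = true == name
        if y.any() and not y.all():
            aucs.append(roc_auc(scores[:, k], y))
    if not aucs:
        raise ValueError("no class with both positives and negatives")
    return float(np.mean(aucs))


def cv_percent(series: ReplicateSeries) -> float:
    """Coefficient of variation: 100 * sample SD (n-1) / mean."""
    v = np.asarray(series.values, dtype=np.float64)
    mean = v.mean()
    if mean == 0:
        raise ValueError("%CV undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / abs(mean))


def limit_of_detection(
    blank_replicates: Sequence[float],
    calibration_slope: float,
    k: float = 3.0,
) -> float:
    """Blank-based LOD: ``k * SD(blank) / slope`` in assay units.

    ``blank_replicates`` are repeated signal readings of the blank (n = 5 in
    the standard protocol); ``calibration_slope`` is the low-range
    signal-per-concentration slope; ``k`` defaults to the conventional 3.
    """
    b = np.asarray(blank_replicates, dtype=np.float64)
    if b.size < 2:
        raise ValueError("need at least 2 blank replicates")
    if calibration_slope <= 0:
        raise ValueError("calibration slope must be positive")
    return float(k * b.std(ddof=1) / calibration_slope)


def dilution_advice(
    pred: float, assay: AssayDefinition, factor: int = 5
) -> DilutionAdvice:
    """Advise a 1:factor dilution when a reading exceeds the validated range."""
    if pred < 0:
        raise ValueError("prediction must be >= 0")
    high = assay.detection_range[1]
    if pred > high:
        return DilutionAdvice(
            needs_dilution=True,
            factor=factor,
            message=(
                f"{assay.name} reading {pred:g} {assay.units} exceeds the "
                f"validated range (top {high:g}); dilute 1:{factor} with "
                "reagent diluent or deionized water, re-measure, and multiply "
                f"the result by {factor}"
            ),
        )
    return DilutionAdvice(needs_dilution=False, factor=factor)


def corrected_after_dilution(measured: float, factor: int = 5) -> float:
    """Reported concentration after a 1:factor dilution re-measurement."""
    return measured * factor


def agreement_report(pairs_by_analyte: Dict[str, PairedMeasurements]) -> pd.DataFrame:
    """Comparative table: per-sample % variation, CLIA check and Pearson r.

    One row per (analyte, sample pair); the r column repeats the analyte's
    correlation (NaN when fewer than 2 pairs or a constant sequence makes
    it undefined).
    """
    rows = []
    for analyte, pairs in pairs_by_analyte.items():
        try:
            r = pearson_r(pairs)
        except ValueError:
            r = float("nan")
        for xi, yi in zip(pairs.x, pairs.y):
            rows.append(
                {
                    "analyte": analyte,
                    "commercial": xi,
                    "developed": yi,
                    "percent_variation": percent_variation(xi, yi),
                    "clia_pass": clia_check(xi, yi),
                    "pearson_r": r,
                }
            )
    return pd.DataFrame(rows)
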