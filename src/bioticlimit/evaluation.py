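"""Model evaluation: confusion-matrix indices, threshold-sweep curves and
their areas, rank-based ROC AUC, point-biserial correlation, and max-Kappa
binarization.

All threshold-dependent indices derive from the confusion matrix of test
presences vs pseudo-absences under the rule "predicted present iff score >=
t". Four of them — Kappa, overall performance (correct classification rate),
commission (false-positive) rate, and omission (false-negative) rate — are
swept over a fixed threshold grid and summarized by the area under the
threshold curve (trapezoid rule, normalized by the grid span so a constant
metric c integrates to c). ROC AUC is the threshold-independent Mann-Whitney
statistic with the usual half-credit for ties. Commission gets special
weight downstream: it is the overprediction measure used to ask whether a
model claims habitat beyond the species' range margin.

Degenerate-margin conventions (documented, tested): commission = 0 when
fp + tn = 0, omission = 0 when fn + tp = 0, kappa = 0 when expected
agreement is 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .spatial import RasterGrid

DEFAULT_THRESHOLDS = np.round(np.linspace(0.0, 1.0, 101), 10)

METRICS = ("kappa", "overall_performance", "commission", "omission")


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Confusion matrix and per-threshold indices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise EvaluationError("confusion counts must be nonnegative")
        if self.n == 0:
            raise EvaluationError("empty confusion matrix")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_at(scores, labels, t: float) -> ConfusionMatrix:
    """Confusion matrix at threshold ``t``; predicted positive iff score >= t."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if not ((labels == 1).any() and (labels == 0).any()):
        raise EvaluationError("need at least one presence and one pseudo-absence")
    pos = scores >= t
    tp = int(np.sum(pos & (labels == 1)))
    fp = int(np.sum(pos & (labels == 0)))
    fn = int(np.sum(~pos & (labels == 1)))
    tn = int(np.sum(~pos & (labels == 0)))
    return ConfusionMatrix(tp, fp, fn, tn)


def metric_suite(cm: ConfusionMatrix) -> dict[str, float]:
    """Kappa, overall performance, commission and omission rates from one
    confusion matrix, with the degenerate-margin conventions."""
    n = cm.n
    p_o = (cm.tp + cm.tn) / n
    commission = cm.fp / (cm.fp + cm.tn) if (cm.fp + cm.tn) > 0 else 0.0
    omission = cm.fn / (cm.fn + cm.tp) if (cm.fn + cm.tp) > 0 else 0.0
    p_e = ((cm.tp + cm.fp) * (cm.tp + cm.fn) + (cm.fn + cm.tn) * (cm.fp + cm.tn)) / n**2
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else 0.0
    return {
        "kappa": kappa,
        "overall_performance": p_o,
        "commission": commission,
        "omission": omission,
    }


# ---------------------------------------------------------------------------
# Threshold sweeps
# ---------------------------------------------------------------------------


@dataclass
class ThresholdCurve:
    thresholds: np.ndarray
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.thresholds.shape != self.values.shape:
            raise EvaluationError("thresholds and values must have equal length")
        if np.any(np.diff(self.thresholds) <= 0):
            raise EvaluationError("thresholds must be strictly increasing")


def threshold_curve(scores, labels, metric: str, grid=None) -> ThresholdCurve:
    if metric not in METRICS:
        raise EvaluationError(f"unknown metric {metric!r}")
    grid = DEFAULT_THRESHOLDS if grid is None else np.asarray(grid, dtype=float)
    values = np.array([metric_suite(confusion_at(scores, labels, t))[metric] for t in grid])
    return ThresholdCurve(grid, values, metric)


def auc_of_curve(curve: ThresholdCurve) -> float:
    """Trapezoid area under the curve, normalized by the threshold span."""
    span = curve.thresholds[-1] - curve.thresholds[0]
    return float(np.trapezoid(curve.values, curve.thresholds) / span)


# ---------------------------------------------------------------------------
# Threshold-independent indices
# ---------------------------------------------------------------------------


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(presence score > absence score) + half ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise EvaluationError("both classes must be nonempty")
    ranks = rankdata(scores)  # midranks handle ties
    r1 = ranks[labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def pearson_cor(scores, labels) -> float:
    """Point-biserial correlation between 0/1 labels and continuous scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if not ((labels == 1).any() and (labels == 0).any()):
        raise EvaluationError("both classes must be nonempty")
    if np.std(scores) == 0:
        raise EvaluationError("zero-variance predictions: correlation undefined")
    return float(np.corrcoef(labels, scores)[0, 1])


# ---------------------------------------------------------------------------
# Max-Kappa binarization
# ---------------------------------------------------------------------------


def max_kappa_threshold(scores, labels, grid=None) -> float:
    """Smallest grid threshold attaining the maximum Kappa."""
    grid = DEFAULT_THRESHOLDS if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise EvaluationError("empty threshold grid")
    curve = threshold_curve(scores, labels, "kappa", grid)
    best = np.flatnonzero(curve.values == curve.values.max())[0]
    return float(grid[best])


def binarize(raster: RasterGrid, t: float) -> RasterGrid:
    values = (raster.values >= t).astype(float)
    values[raster.nodata_mask] = 0.0
    return RasterGrid(raster.spec, values, raster.nodata_mask.copy(), name=f"{raster.name}_bin")


# ---------------------------------------------------------------------------
# The six-index report
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    auc_roc: float
    auc_kappa: float
    auc_overall_performance: float
    auc_commission: float
    auc_omission: float
    pearson_cor: float
    max_kappa_threshold: float
    curves: dict[str, ThresholdCurve] = field(default_factory=dict)

    def indices(self) -> dict[str, float]:
        return {
            "auc_roc": self.auc_roc,
            "auc_kappa": self.auc_kappa,
            "auc_overall_performance": self.auc_overall_performance,
            "auc_commission": self.auc_commission,
            "auc_omission": self.auc_omission,
            "pearson_cor": self.pearson_cor,
        }


#: Whether a larger value of each index means a better model.
HIGHER_IS_BETTER = {
    "auc_roc": True,
    "auc_kappa": True,
    "auc_overall_performance": True,
    "auc_commission": False,
    "auc_omission": False,
    "pearson_cor": True,
}


def evaluate(scores, labels, grid=None) -> EvaluationReport:
    """Compute all six indices and the four threshold curves in one pass."""
    grid = DEFAULT_THRESHOLDS if grid is None else np.asarray(grid, dtype=float)
    curves = {m: threshold_curve(scores, labels, m, grid) for m in METRICS}
    return EvaluationReport(
        auc_roc=roc_auc(scores, labels),
        auc_kappa=auc_of_curve(curves["kappa"]),
        auc_overall_performance=auc_of_curve(curves["overall_performance"]),
        auc_commission=auc_of_curve(curves["commission"]),
        auc_omission=auc_of_curve(curves["omission"]),
        pearson_cor=pearson_cor(scores, labels),
        max_kappa_threshold=float(
            grid[np.flatnonzero(curves["kappa"].values == curves["kappa"].values.max())[0]]
        ),
        curves=curves,
    )
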