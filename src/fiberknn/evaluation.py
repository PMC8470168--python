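"""Performance metrics, fiber-density classification, and supply summaries.

Regression metrics are R-squared, mean absolute error, and Spearman rank
correlation.  Predicted fiber is also banded into four density classes
(negligible / low / medium / high at 0.9, 3.7 and 7.3 g per 100 g or 100 mL,
the fiber-point cut-offs of the Australian Health Star Rating scheme) and
scored with accuracy / precision / recall.  Supply-level reporting gives
median (IQR) fiber per category, pooling label values for reporters with
model predictions for non-reporters, plus a rank-sum comparison of the two
groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from fiberknn.knn import FiberModel, Prediction, predict_many
from fiberknn.products import ProductTable

logger = logging.getLogger(__name__)

#: Density-class boundaries in g per 100 g or 100 mL (lower-inclusive).
DENSITY_BOUNDS = (0.9, 3.7, 7.3)


class DensityClass(IntEnum):
    """Fiber density band; ordering follows increasing fiber."""

    NEGLIGIBLE = 0
    LOW = 1
    MEDIUM = 2
    HIGH = 3

    @property
    def label(self) -> str:
        return self.name.lower()


@dataclass
class ClassificationBlock:
    """Accuracy, per-class precision/recall, and a 4x4 confusion matrix.

    Precision (recall) for a class with no predicted (true) instances is
    ``None`` — undefined, not zero.  Confusion rows are truth, columns are
    prediction, both in DensityClass order.
    """

    accuracy: float
    precision: dict[DensityClass, Optional[float]]
    recall: dict[DensityClass, Optional[float]]
    confusion: np.ndarray

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": {c.label: self.precision[c] for c in DensityClass},
            "recall": {c.label: self.recall[c] for c in DensityClass},
            "confusion": self.confusion.tolist(),
            "confusion_labels": [c.label for c in DensityClass],
        }


@dataclass
class MetricsReport:
    """Regression (and optionally classification) metrics for one scope."""

    scope: str
    n: int
    r2: Optional[float]
    mae: float
    spearman_rho: Optional[float]
    classification: Optional[ClassificationBlock] = None

    def to_dict(self) -> dict:
        d = {
            "scope": self.scope,
            "n": self.n,
            "r2": self.r2,
            "mae": self.mae,
            "spearman_rho": self.spearman_rho,
        }
        if self.classification is not None:
            d["classification"] = self.classification.to_dict()
        return d


@dataclass
class SupplyRow:
    """One category's (or the total) supply-level fiber summary."""

    category: str
    n_reporting: int
    pct_reporting: float
    reported_median: Optional[float]
    reported_iqr: Optional[float]
    n_nonreporting: int
    predicted_median: Optional[float]
    predicted_iqr: Optional[float]
    n_total: int
    pooled_median: Optional[float]
    pooled_iqr: Optional[float]


@dataclass
class SupplySummary:
    """Per-category rows + total row + reported-vs-predicted group comparison."""

    rows: list[SupplyRow]
    total: SupplyRow
    statistic: Optional[float]
    p_value: Optional[float]
    unpredictable_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "rows": [vars(r) for r in self.rows],
            "total": vars(self.total),
            "rank_sum_statistic": self.statistic,
            "rank_sum_p_value": self.p_value,
            "unpredictable_ids": self.unpredictable_ids,
        }


def _as_arrays(reported, predicted, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(list(reported), dtype=float)
    yhat = np.asarray(list(predicted), dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if len(y) < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {len(y)}")
    return y, yhat


def r_squared(reported: Sequence[float], predicted: Sequence[float]) -> float:
    """1 - SS_res / SS_tot; can be negative for predictions worse than the mean."""
    y, yhat = _as_arrays(reported, predicted, min_n=2)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: all reported values are identical")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def mae(reported: Sequence[float], predicted: Sequence[float]) -> float:
    """Mean absolute error in g per basis."""
    y, yhat = _as_arrays(reported, predicted, min_n=1)
    return float(np.mean(np.abs(y - yhat)))


def spearman_rho(reported: Sequence[float], predicted: Sequence[float]) -> float:
    """Pearson correlation of (tie-averaged) ranks."""
    y, yhat = _as_arrays(reported, predicted, min_n=2)
    ry = stats.rankdata(y)
    rp = stats.rankdata(yhat)
    if np.ptp(ry) == 0 or np.ptp(rp) == 0:
        raise ValueError("Spearman rho undefined: zero rank variance")
    return float(np.corrcoef(ry, rp)[0, 1])


def classify_density(fiber: float) -> DensityClass:
    """Band a fiber value (g per 100 g or 100 mL); boundaries lower-inclusive."""
    if fiber < 0:
        raise ValueError(f"fiber must be >= 0, got {fiber}")
    return DensityClass(int(np.searchsorted(DENSITY_BOUNDS, fiber, side="right")))


def classification_metrics(
    true_classes: Sequence[DensityClass],
    predicted_classes: Sequence[DensityClass],
) -> ClassificationBlock:
    """Accuracy, per-class precision/recall, and the confusion matrix."""
    if len(true_classes) != len(predicted_classes):
        raise ValueError("length mismatch")
    if len(true_classes) == 0:
        raise ValueError("need at least 1 pair")
    confusion = np.zeros((4, 4), dtype=int)
    for t, p in zip(true_classes, predicted_classes):
        confusion[int(t), int(p)] += 1
    total = confusion.sum()
    accuracy = float(np.trace(confusion)) / total
    precision: dict[DensityClass, Optional[float]] = {}
    recall: dict[DensityClass, Optional[float]] = {}
    for c in DensityClass:
        col = confusion[:, int(c)].sum()  # TP + FP
        row = confusion[int(c), :].sum()  # TP + FN
        tp = confusion[int(c), int(c)]
        precision[c] = float(tp) / col if col > 0 else None
        recall[c] = float(tp) / row if row > 0 else None
    return ClassificationBlock(accuracy, precision, recall, confusion)


def compute_metrics(
    reported: Sequence[float],
    predicted: Sequence[float],
    scope: str = "overall",
    with_classification: bool = True,
) -> MetricsReport:
    """Build a MetricsReport; R^2 / rho are None when undefined for the scope."""
    y, yhat = _as_arrays(reported, predicted, min_n=1)
    try:
        r2 = r_squared(y, yhat)
    except ValueError:
        r2 = None
    try:
        rho = spearman_rho(y, yhat)
    except ValueError:
        rho = None
    block = None
    if with_classification:
        block = classification_metrics(
            [classify_density(v) for v in y],
            [classify_density(max(v, 0.0)) for v in yhat],
        )
    return MetricsReport(scope, len(y), r2, mae(y, yhat), rho, block)


def stratify_by_d1(
    predictions: Sequence[Prediction],
    reported: Mapping[str, float],
) -> list[MetricsReport]:
    """Split scored predictions into quartiles of d1 and report metrics per group.

    Edges are the 25th/50th/75th linear-interpolation percentiles of the d1
    values of the evaluated set; groups are lower-inclusive on edges.
    """
    scored = [p for p in predictions if p.product_id in reported]
    if len(scored) < 4:
        raise ValueError(f"need at least 4 scored predictions, got {len(scored)}")
    d1 = np.array([p.d1 for p in scored])
    edges = np.percentile(d1, [25, 50, 75])
    group = np.searchsorted(edges, d1, side="right")
    reports = []
    for g in range(4):
        members = [p for p, grp in zip(scored, group) if grp == g]
        lo = edges[g - 1] if g > 0 else d1.min()
        hi = edges[g] if g < 3 else d1.max()
        scope = f"d1_quartile_{g + 1} [{lo:.4f}, {hi:.4f}]"
        if not members:
            reports.append(MetricsReport(scope, 0, None, float("nan"), None))
            continue
        reports.append(
            compute_metrics(
                [reported[p.product_id] for p in members],
                [p.predicted_fiber for p in members],
                scope=scope,
            )
        )
    return reports


def compare_reporting_groups(
    reported_fibers: Sequence[float],
    predicted_fibers_of_nonreporters: Sequence[float],
) -> tuple[float, float]:
    """Two-sided rank-sum (Mann-Whitney U) comparison of two independent groups.

    Exact p by enumeration when min(n1, n2) <= 8 and there are no ties;
    otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(list(reported_fibers), dtype=float)
    b = np.asarray(list(predicted_fibers_of_nonreporters), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and no_ties) else "asymptotic"
    result = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(result.statistic), float(result.pvalue)


def _median_iqr(values: Sequence[float]) -> tuple[Optional[float], Optional[float]]:
    if len(values) == 0:
        return None, None
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q3 - q1)


def supply_summary(table: ProductTable, model: FiberModel) -> SupplySummary:
    """Median (IQR) fiber per category and overall across the whole supply.

    Reporters contribute their label fiber; non-reporters contribute model
    predictions.  Non-reporters in categories absent from the model are
    excluded from the predicted summaries and listed in
    ``unpredictable_ids``.  Attaches the rank-sum comparison of reported vs
    predicted values.
    """
    reporters = ProductTable([r for r in table.records if r.fiber is not None])
    nonreporters = ProductTable([r for r in table.records if r.fiber is None])
    predictions, skipped = predict_many(model, nonreporters, skip_unknown_categories=True)
    if skipped:
        logger.warning(
            "supply_summary: %d non-reporting products in categories unknown to "
            "the model were excluded from predicted summaries", len(skipped),
        )
    predicted_by_id = {p.product_id: p.predicted_fiber for p in predictions}

    categories = table.categories()
    rows: list[SupplyRow] = []
    all_reported: list[float] = []
    all_predicted: list[float] = []
    for cat in sorted(categories):
        rep = [r.fiber for r in reporters.records if r.category == cat]
        nonrep_ids = [r.product_id for r in nonreporters.records if r.category == cat]
        pred = [predicted_by_id[i] for i in nonrep_ids if i in predicted_by_id]
        n_total = len(rep) + len(nonrep_ids)
        rep_med, rep_iqr = _median_iqr(rep)
        pred_med, pred_iqr = _median_iqr(pred)
        pooled_med, pooled_iqr = _median_iqr(rep + pred)
        rows.append(
            SupplyRow(
                category=cat,
                n_reporting=len(rep),
                pct_reporting=100.0 * len(rep) / n_total if n_total else 0.0,
                reported_median=rep_med,
                reported_iqr=rep_iqr,
                n_nonreporting=len(nonrep_ids),
                predicted_median=pred_med,
                predicted_iqr=pred_iqr,
                n_total=n_total,
                pooled_median=pooled_med,
                pooled_iqr=pooled_iqr,
            )
        )
        all_reported.extend(rep)
        all_predicted.extend(pred)

    n_total = len(table)
    tot_rep_med, tot_rep_iqr = _median_iqr(all_reported)
    tot_pred_med, tot_pred_iqr = _median_iqr(all_predicted)
    tot_pooled_med, tot_pooled_iqr = _median_iqr(all_reported + all_predicted)
    total = SupplyRow(
        category="total",
        n_reporting=len(all_reported),
        pct_reporting=100.0 * len(all_reported) / n_total if n_total else 0.0,
        reported_median=tot_rep_med,
        reported_iqr=tot_rep_iqr,
        n_nonreporting=len(nonreporters),
        predicted_median=tot_pred_med,
        predicted_iqr=tot_pred_iqr,
        n_total=n_total,
        pooled_median=tot_pooled_med,
        pooled_iqr=tot_pooled_iqr,
    )

    statistic = p_value = None
    if all_reported and all_predicted:
        statistic, p_value = compare_reporting_groups(all_reported, all_predicted)
    return SupplySummary(rows, total, statistic, p_value, skipped)
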