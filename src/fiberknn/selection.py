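"""Brand-grouped train/test splitting and cross-validated hyperparameter search.

Products of one brand travel together across the split so that near-identical
formulations (flavor variants of the same product line) can never leak between
training and test sets.  Hyperparameters are chosen by five-fold
cross-validated R-squared on the training set, ties broken toward the simpler
configuration (smaller k, Manhattan before Euclidean, inverse before uniform).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from fiberknn.evaluation import r_squared
from fiberknn.knn import Hyperparams, fit, predict_many
from fiberknn.products import ProductTable

logger = logging.getLogger(__name__)

_METRIC_RANK = {"manhattan": 0, "euclidean": 1}
_WEIGHT_RANK = {"inverse": 0, "uniform": 1}


@dataclass(frozen=True)
class SplitSpec:
    """Brand-grouped split specification."""

    train_fraction: float = 0.75
    seed: int = 0
    grouping: str = "brand"

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError(f"train_fraction must be in (0, 1), got {self.train_fraction}")
        if self.grouping != "brand":
            raise ValueError("only brand grouping is supported")


@dataclass
class CVRow:
    hyper: Hyperparams
    fold_scores: list[Optional[float]]
    mean_r2: Optional[float]


@dataclass
class CVResult:
    """Grid-search result: one row per configuration, sorted by mean R^2."""

    rows: list[CVRow]
    folds: int
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        data = []
        for row in self.rows:
            d = {
                "metric": row.hyper.metric,
                "weighting": row.hyper.weighting,
                "k": row.hyper.k,
            }
            for i, s in enumerate(row.fold_scores):
                d[f"fold_{i}"] = s
            d["mean_r2"] = row.mean_r2
            data.append(d)
        return pd.DataFrame(data)


def brand_grouped_split(
    table: ProductTable, spec: SplitSpec
) -> tuple[ProductTable, ProductTable]:
    """Randomly allocate whole brands to train/test.

    Operates on the fiber-reporting subset: every record must carry both a
    fiber value and a brand.  Brands are shuffled with the spec's seed and the
    first ceil(train_fraction * B) go to training.  Deterministic per seed.
    """
    for r in table.records:
        if r.fiber is None:
            raise ValueError(
                f"record {r.product_id!r} has no fiber value; split the reporting subset"
            )
        if not r.brand.strip():
            raise ValueError(f"record {r.product_id!r} has no brand")

    brands = sorted(set(r.brand for r in table.records))
    if len(brands) < 2:
        raise ValueError(f"need at least 2 brands to split, got {len(brands)}")
    rng = np.random.default_rng(spec.seed)
    shuffled = [brands[i] for i in rng.permutation(len(brands))]
    n_train = math.ceil(spec.train_fraction * len(brands))
    train_brands = set(shuffled[:n_train])
    train = ProductTable(
        [r for r in table.records if r.brand in train_brands],
        provenance=f"{table.provenance} [train seed={spec.seed}]",
    )
    test = ProductTable(
        [r for r in table.records if r.brand not in train_brands],
        provenance=f"{table.provenance} [test seed={spec.seed}]",
    )
    logger.info(
        "brand split: %d/%d brands, %d/%d products (train/test)",
        n_train, len(brands) - n_train, len(train), len(test),
    )
    return train, test


def default_grid(max_k: int = 20) -> list[Hyperparams]:
    """Metric x weighting x k in 1..max_k."""
    return [
        Hyperparams(k=k, metric=m, weighting=w)
        for m in ("manhattan", "euclidean")
        for w in ("inverse", "uniform")
        for k in range(1, max_k + 1)
    ]


def kfold_cv(
    train: ProductTable,
    grid: Sequence[Hyperparams],
    folds: int = 5,
    seed: int = 0,
) -> CVResult:
    """Product-level k-fold cross-validation of a hyperparameter grid.

    Products are shuffled once with ``seed`` and dealt into near-equal folds.
    For each fold the model (including normalization parameters) is refit on
    the out-of-fold data; held-out products whose category is absent from the
    fold's stores are skipped.  A fold with no scorable products (or a
    degenerate R^2) is recorded as missing and excluded from the mean.
    Rows are sorted by descending mean R^2 (missing means last).
    """
    if folds < 2:
        raise ValueError(f"folds must be >= 2, got {folds}")
    if len(train) == 0:
        raise ValueError("training table is empty")
    if not grid:
        raise ValueError("hyperparameter grid is empty")

    n = len(train)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % folds

    scores: list[list[Optional[float]]] = [[] for _ in grid]
    for f in range(folds):
        in_fold = ProductTable([r for r, g in zip(train.records, fold_of) if g == f])
        out_fold = ProductTable([r for r, g in zip(train.records, fold_of) if g != f])
        base = fit(out_fold)  # stores/normalization are hyperparameter-free
        reported = {r.product_id: r.fiber for r in in_fold.records}
        for gi, hyper in enumerate(grid):
            preds, skipped = predict_many(
                base.with_hyper(hyper), in_fold, skip_unknown_categories=True
            )
            if skipped:
                logger.warning(
                    "fold %d, %s: skipped %d products in categories absent from fold training",
                    f, hyper, len(skipped),
                )
            y = [reported[p.product_id] for p in preds]
            yhat = [p.predicted_fiber for p in preds]
            try:
                score = r_squared(y, yhat)
            except ValueError:
                logger.warning("fold %d, %s: R^2 undefined; fold recorded as missing", f, hyper)
                score = None
            scores[gi].append(score)

    rows = []
    for hyper, fold_scores in zip(grid, scores):
        defined = [s for s in fold_scores if s is not None]
        mean = float(np.mean(defined)) if defined else None
        rows.append(CVRow(hyper, fold_scores, mean))
    rows.sort(key=lambda r: (-(r.mean_r2 if r.mean_r2 is not None else -np.inf),))
    return CVResult(rows=rows, folds=folds, seed=seed)


def select_hyperparameters(cv: CVResult) -> Hyperparams:
    """Highest mean R^2; ties go to smaller k, then Manhattan, then inverse."""
    candidates = [r for r in cv.rows if r.mean_r2 is not None]
    if not candidates:
        raise ValueError("no configuration has a defined mean R^2")
    best = min(
        candidates,
        key=lambda r: (
            -r.mean_r2,
            r.hyper.k,
            _METRIC_RANK[r.hyper.metric],
            _WEIGHT_RANK[r.hyper.weighting],
        ),
    )
    return best.hyper
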