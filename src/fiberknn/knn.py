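"""Category-restricted weighted k-nearest-neighbor fiber prediction.

A fitted model holds the normalization parameters plus one training store per
food category; neighbor search is an exhaustive scan within the query's
category (a hard partition — the reference semantics).  Prediction is an
inverse-distance-weighted average of the k nearest neighbors' fiber values,
with ties at the cut broken by ascending product id and exact matches
(distance zero) averaged unweighted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from fiberknn.features import (
    FeatureVector,
    N_FEATURES,
    NormalizationParams,
    derive_features,
    feature_matrix,
    fit_normalization,
    normalize,
)
from fiberknn.products import ProductRecord, ProductTable

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

METRICS = ("manhattan", "euclidean")
WEIGHTINGS = ("inverse", "uniform")

_CDIST_METRIC = {"manhattan": "cityblock", "euclidean": "euclidean"}

#: Default first-neighbor distance above which a prediction is flagged.
DEFAULT_CAUTION_THRESHOLD = 0.08


@dataclass(frozen=True)
class Hyperparams:
    """KNN hyperparameters: neighbor count, distance metric, weighting."""

    k: int = 8
    metric: str = "manhattan"
    weighting: str = "inverse"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}, got {self.metric!r}")
        if self.weighting not in WEIGHTINGS:
            raise ValueError(f"weighting must be one of {WEIGHTINGS}, got {self.weighting!r}")

    def to_dict(self) -> dict:
        return {"k": self.k, "metric": self.metric, "weighting": self.weighting}

    @classmethod
    def from_dict(cls, d: dict) -> "Hyperparams":
        return cls(int(d["k"]), d["metric"], d["weighting"])


@dataclass
class CategoryStore:
    """Normalized training products of one category (all with known fiber)."""

    ids: np.ndarray          # (n,) str
    features: np.ndarray     # (n, 6) normalized
    fiber: np.ndarray        # (n,) g per basis

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class Neighbor:
    product_id: str
    distance: float
    weight: float
    fiber: float


@dataclass(frozen=True)
class Prediction:
    """A fiber prediction with full neighbor provenance."""

    product_id: str
    predicted_fiber: float
    neighbors: tuple[Neighbor, ...]
    d1: float
    k_effective: int
    caution: bool


@dataclass
class FiberModel:
    """Normalization params + per-category training stores + hyperparameters."""

    params: NormalizationParams
    stores: dict[str, CategoryStore]
    hyper: Hyperparams = field(default_factory=Hyperparams)
    caution_threshold: float = DEFAULT_CAUTION_THRESHOLD

    def categories(self) -> list[str]:
        return sorted(self.stores)

    def n_training(self) -> int:
        return sum(len(s) for s in self.stores.values())

    def with_hyper(self, hyper: Hyperparams) -> "FiberModel":
        """Same fitted stores under different hyperparameters (shared arrays)."""
        return replace(self, hyper=hyper)

    # -- serialization -------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "params": self.params.to_dict(),
            "hyper": self.hyper.to_dict(),
            "caution_threshold": self.caution_threshold,
            "stores": {
                cat: [
                    [str(pid), [float(x) for x in row], float(q)]
                    for pid, row, q in zip(s.ids, s.features, s.fiber)
                ]
                for cat, s in sorted(self.stores.items())
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "FiberModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {payload.get('format_version')!r}"
            )
        stores = {}
        for cat, rows in payload["stores"].items():
            stores[cat] = CategoryStore(
                ids=np.array([r[0] for r in rows], dtype=str),
                features=np.array([r[1] for r in rows], dtype=float),
                fiber=np.array([r[2] for r in rows], dtype=float),
            )
        return cls(
            params=NormalizationParams.from_dict(payload["params"]),
            stores=stores,
            hyper=Hyperparams.from_dict(payload["hyper"]),
            caution_threshold=float(payload["caution_threshold"]),
        )


def manhattan_distance(x: FeatureVector | Sequence[float], y: FeatureVector | Sequence[float]) -> float:
    """Sum of absolute differences over the six normalized features."""
    xa = x.as_array() if isinstance(x, FeatureVector) else np.asarray(x, dtype=float)
    ya = y.as_array() if isinstance(y, FeatureVector) else np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError(f"length mismatch: {xa.shape} vs {ya.shape}")
    return float(np.abs(xa - ya).sum())


def fit(
    training: ProductTable,
    hyper: Optional[Hyperparams] = None,
    caution_threshold: float = DEFAULT_CAUTION_THRESHOLD,
) -> FiberModel:
    """Fit a model: normalization on the training set, stores per category.

    Every training record must have a fiber value.
    """
    for r in training.records:
        if r.fiber is None:
            raise ValueError(f"training record {r.product_id!r} has no fiber value")
    if len(training) < 2:
        raise ValueError("need at least 2 training records")

    raw = feature_matrix(training)
    params = fit_normalization(raw, fitted_on=training.provenance)
    norm = normalize(raw, params)

    stores: dict[str, CategoryStore] = {}
    cats = np.array([r.category for r in training.records])
    ids = np.array([r.product_id for r in training.records], dtype=str)
    fiber = np.array([r.fiber for r in training.records], dtype=float)
    for cat in dict.fromkeys(cats.tolist()):
        mask = cats == cat
        stores[cat] = CategoryStore(ids=ids[mask], features=norm[mask], fiber=fiber[mask])
    return FiberModel(
        params=params,
        stores=stores,
        hyper=hyper or Hyperparams(),
        caution_threshold=caution_threshold,
    )


def _prediction_from_distances(
    model: FiberModel,
    store: CategoryStore,
    dists: np.ndarray,
    query_id: str,
) -> Prediction:
    """Shared selection/weighting logic for single and batch prediction."""
    mask = store.ids != query_id  # leave-self-out by id
    ids = store.ids[mask]
    d = dists[mask]
    q = store.fiber[mask]
    if len(ids) == 0:
        raise ValueError(
            f"no eligible neighbors for {query_id!r} (store contains only the query itself)"
        )
    order = np.lexsort((ids, d))  # distance first, ascending id breaks ties
    k_eff = min(model.hyper.k, len(ids))
    sel = order[:k_eff]
    d_sel, q_sel, id_sel = d[sel], q[sel], ids[sel]

    zero = d_sel == 0.0
    if zero.any():
        # 1/d is undefined at 0: average the exact matches unweighted
        weights = zero.astype(float)
        predicted = float(q_sel[zero].mean())
    elif model.hyper.weighting == "inverse":
        weights = 1.0 / d_sel
        predicted = float(np.dot(weights, q_sel) / weights.sum())
    else:
        weights = np.ones(k_eff)
        predicted = float(q_sel.mean())

    d1 = float(d_sel[0])
    return Prediction(
        product_id=query_id,
        predicted_fiber=predicted,
        neighbors=tuple(
            Neighbor(str(i), float(dd), float(w), float(ff))
            for i, dd, w, ff in zip(id_sel, d_sel, weights, q_sel)
        ),
        d1=d1,
        k_effective=k_eff,
        caution=d1 > model.caution_threshold,
    )


def predict(model: FiberModel, query: ProductRecord) -> Prediction:
    """Predict fiber for one product from its category's training store."""
    store = model.stores.get(query.category)
    if store is None:
        raise ValueError(
            f"unknown category {query.category!r}; known: {model.categories()}"
        )
    vec = normalize(derive_features(query), model.params).as_array()
    dists = cdist(vec[None, :], store.features, metric=_CDIST_METRIC[model.hyper.metric])[0]
    return _prediction_from_distances(model, store, dists, query.product_id)


def predict_many(
    model: FiberModel,
    queries: ProductTable,
    skip_unknown_categories: bool = False,
) -> tuple[list[Prediction], list[str]]:
    """Batch prediction; distances are computed category-wise in one pass.

    Returns (predictions in input order, skipped product ids).  With
    ``skip_unknown_categories`` false, an unknown category raises.
    """
    predictions: dict[str, Prediction] = {}
    skipped: list[str] = []
    by_cat: dict[str, list[ProductRecord]] = {}
    for r in queries.records:
        by_cat.setdefault(r.category, []).append(r)

    for cat, records in by_cat.items():
        store = model.stores.get(cat)
        if store is None:
            if not skip_unknown_categories:
                raise ValueError(f"unknown category {cat!r}; known: {model.categories()}")
            skipped.extend(r.product_id for r in records)
            continue
        raw = np.array([derive_features(r).values for r in records], dtype=float)
        norm = normalize(raw, model.params)
        dmat = cdist(norm, store.features, metric=_CDIST_METRIC[model.hyper.metric])
        for r, dists in zip(records, dmat):
            predictions[r.product_id] = _prediction_from_distances(
                model, store, dists, r.product_id
            )
    ordered = [predictions[r.product_id] for r in queries.records if r.product_id in predictions]
    return ordered, skipped


def explain(prediction: Prediction, model: FiberModel) -> str:
    """Human-readable neighbor report with weight shares summing to one."""
    total_weight = sum(n.weight for n in prediction.neighbors)
    lines = [
        f"prediction for {prediction.product_id}: "
        f"{prediction.predicted_fiber:.3f} g fiber "
        f"(d1={prediction.d1:.4f}, k={prediction.k_effective}"
        f"{', CAUTION: sparse neighborhood' if prediction.caution else ''})"
    ]
    for rank, n in enumerate(prediction.neighbors, start=1):
        share = n.weight / total_weight if total_weight > 0 else 0.0
        tag = "  [exact match]" if n.distance == 0.0 else ""
        lines.append(
            f"  {rank}. {n.product_id}: distance={n.distance:.4f} "
            f"weight_share={share:.3f} fiber={n.fiber:.3f} g{tag}"
        )
    return "\n".join(lines)


def predictions_to_rows(predictions: Iterable[Prediction]) -> list[dict]:
    """Flatten predictions for CSV export."""
    return [
        {
            "product_id": p.product_id,
            "predicted_fiber_g": p.predicted_fiber,
            "d1": p.d1,
            "k_effective": p.k_effective,
            "caution": p.caution,
            "neighbor_ids": ";".join(n.product_id for n in p.neighbors),
        }
        for p in predictions
    ]
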