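"""Six-nutrient feature derivation and training-set min-max normalization.

Feature order is fixed: (total_sugar, starch, protein, saturated_fat,
unsaturated_fat, sodium).  Starch is carbohydrate minus total sugar and
unsaturated fat is total fat minus saturated fat; a negative derived value
(a label rounding artifact) is clamped to zero with a warning.  Sodium stays
in mg — min-max scaling makes the unit immaterial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from fiberknn.products import ProductRecord, ProductTable

logger = logging.getLogger(__name__)

#: Fixed feature order.
FEATURE_NAMES = (
    "total_sugar",
    "starch",
    "protein",
    "saturated_fat",
    "unsaturated_fat",
    "sodium",
)

N_FEATURES = len(FEATURE_NAMES)


@dataclass(frozen=True)
class FeatureVector:
    """Six ordered feature values plus a normalization flag.

    Raw values are non-negative by construction (clamping); normalized values
    for query products may fall outside [0, 1] — there is no clipping.
    """

    values: tuple[float, float, float, float, float, float]
    normalized: bool = False

    def __post_init__(self) -> None:
        if len(self.values) != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES} features, got {len(self.values)}")
        if not self.normalized and any(v < 0 for v in self.values):
            raise ValueError(f"raw feature values must be >= 0, got {self.values}")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature training min/max used by the min-max transform."""

    mins: tuple[float, ...]
    maxs: tuple[float, ...]
    fitted_on: str = ""

    def __post_init__(self) -> None:
        if len(self.mins) != N_FEATURES or len(self.maxs) != N_FEATURES:
            raise ValueError("mins and maxs must both have 6 entries")
        for lo, hi in zip(self.mins, self.maxs):
            if lo > hi:
                raise ValueError(f"per-feature min {lo} exceeds max {hi}")

    def to_dict(self) -> dict:
        return {
            "mins": list(self.mins),
            "maxs": list(self.maxs),
            "fitted_on": self.fitted_on,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(tuple(d["mins"]), tuple(d["maxs"]), d.get("fitted_on", ""))


def derive_features(record: ProductRecord) -> FeatureVector:
    """Derive the raw six-feature vector from a record's panel nutrients.

    Negative starch or unsaturated fat (possible when independently rounded
    label values are subtracted) is clamped to 0 and logged.
    """
    if not record.has_panel():
        raise ValueError(f"product {record.product_id!r} is missing mandatory nutrients")
    starch = record.carbohydrate - record.total_sugar
    unsaturated = record.total_fat - record.saturated_fat
    if starch < 0:
        logger.warning(
            "product %s: negative derived starch %.4g clamped to 0",
            record.product_id, starch,
        )
        starch = 0.0
    if unsaturated < 0:
        logger.warning(
            "product %s: negative derived unsaturated fat %.4g clamped to 0",
            record.product_id, unsaturated,
        )
        unsaturated = 0.0
    return FeatureVector(
        (
            float(record.total_sugar),
            float(starch),
            float(record.protein),
            float(record.saturated_fat),
            float(unsaturated),
            float(record.sodium),
        )
    )


def feature_matrix(table: ProductTable) -> np.ndarray:
    """Raw feature matrix (n_records, 6) in table order."""
    return np.array([derive_features(r).values for r in table.records], dtype=float)


def fit_normalization(
    training: Iterable[FeatureVector] | np.ndarray,
    fitted_on: str = "",
) -> NormalizationParams:
    """Fit per-feature min and max over a collection of raw feature vectors.

    Constant features (min == max) are permitted; at least two vectors are
    required.
    """
    if isinstance(training, np.ndarray):
        matrix = np.asarray(training, dtype=float)
    else:
        matrix = np.array([v.as_array() for v in training], dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != N_FEATURES:
        raise ValueError(f"expected a (n, {N_FEATURES}) collection, got shape {matrix.shape}")
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 training vectors to fit normalization")
    return NormalizationParams(
        tuple(matrix.min(axis=0).tolist()),
        tuple(matrix.max(axis=0).tolist()),
        fitted_on,
    )


def normalize(
    v: FeatureVector | np.ndarray,
    params: NormalizationParams,
) -> FeatureVector | np.ndarray:
    """Min-max transform X' = (X - Xmin) / (Xmax - Xmin), without clipping.

    A constant feature maps to 0 (any constant contributes nothing to
    Manhattan distances).  Values outside the training range map outside
    [0, 1].  Accepts a single :class:`FeatureVector` or an (n, 6) array;
    returns the same kind.
    """
    mins = np.asarray(params.mins)
    span = np.asarray(params.maxs) - mins
    safe_span = np.where(span == 0, 1.0, span)
    if isinstance(v, np.ndarray):
        x = np.asarray(v, dtype=float)
        out = (x - mins) / safe_span
        return np.where(span == 0, 0.0, out)
    if v.normalized:
        raise ValueError("feature vector is already normalized")
    out = (v.as_array() - mins) / safe_span
    out = np.where(span == 0, 0.0, out)
    return FeatureVector(tuple(out.tolist()), normalized=True)
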