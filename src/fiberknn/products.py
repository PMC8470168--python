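"""Product records, CSV I/O, and record- and category-level exclusion filters.

Records carry the six mandatory panel nutrients (per 100 g or 100 mL), an
optional fiber value (the prediction target when present) and optional
ingredients text.  Cleaning is a sequential rule pipeline: each product is
logged under the first rule it violates, and category-level filtering drops
categories whose fiber-reporting rate falls below a threshold or that are
outside a user-supplied allow-list.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: The six mandatory panel nutrients, in canonical order.
MANDATORY_NUTRIENTS = (
    "total_sugar",
    "carbohydrate",
    "protein",
    "saturated_fat",
    "total_fat",
    "sodium",
)

#: Record field -> default CSV column name.
DEFAULT_SCHEMA: Mapping[str, str] = {
    "product_id": "product_id",
    "brand": "brand",
    "category": "category",
    "basis": "basis",
    "total_sugar": "total_sugar_g",
    "carbohydrate": "carbohydrate_g",
    "protein": "protein_g",
    "saturated_fat": "saturated_fat_g",
    "total_fat": "total_fat_g",
    "sodium": "sodium_mg",
    "fiber": "fiber_g",
    "ingredients_text": "ingredients_text",
}

#: Canonical exclusion rule order; a record is logged under the first rule hit.
EXCLUSION_RULES = (
    "missing_panel",
    "missing_ingredients",
    "unbalanced_ingredients",
    "missing_brand",
    "duplicate_id",
)


class Basis(str, Enum):
    """Declaration basis of the panel values."""

    PER_100G = "per_100g"
    PER_100ML = "per_100mL"


class SchemaError(ValueError):
    """The CSV header does not satisfy the configured schema."""


class RowParseError(ValueError):
    """A data row could not be parsed into a valid record."""


@dataclass(frozen=True)
class ProductRecord:
    """One packaged product: identity, category, brand, and panel nutrients.

    Mandatory nutrients may be ``None`` at ingest time (panel absent on pack);
    such records are removed by the ``missing_panel`` exclusion rule before
    any modeling.  Present values must be non-negative.
    """

    product_id: str
    brand: str
    category: str
    total_sugar: Optional[float]
    carbohydrate: Optional[float]
    protein: Optional[float]
    saturated_fat: Optional[float]
    total_fat: Optional[float]
    sodium: Optional[float]
    basis: Basis = Basis.PER_100G
    fiber: Optional[float] = None
    ingredients_text: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.product_id:
            raise ValueError("product_id must be non-empty")
        for name in MANDATORY_NUTRIENTS + ("fiber",):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(
                    f"{name} must be >= 0 for product {self.product_id!r}, got {value}"
                )

    def has_panel(self) -> bool:
        """True iff all six mandatory nutrients are present."""
        return all(getattr(self, n) is not None for n in MANDATORY_NUTRIENTS)

    def nutrients(self) -> tuple:
        """The six mandatory nutrient values in canonical order."""
        return tuple(getattr(self, n) for n in MANDATORY_NUTRIENTS)


@dataclass
class ProductTable:
    """An ordered collection of product records with a provenance note."""

    records: list[ProductRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProductRecord]:
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.product_id for r in self.records]

    def categories(self) -> list[str]:
        """Distinct categories in first-appearance order."""
        return list(dict.fromkeys(r.category for r in self.records))

    def brands(self) -> list[str]:
        """Distinct brands in first-appearance order."""
        return list(dict.fromkeys(r.brand for r in self.records))

    def subset(self, keep: Iterable[str], provenance: str = "") -> "ProductTable":
        """Records whose product_id is in ``keep``, original order preserved."""
        keep = set(keep)
        return ProductTable(
            [r for r in self.records if r.product_id in keep],
            provenance or self.provenance,
        )

    def to_dataframe(self, schema: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
        schema = dict(DEFAULT_SCHEMA if schema is None else schema)
        rows = []
        for r in self.records:
            row = {
                schema["product_id"]: r.product_id,
                schema["brand"]: r.brand,
                schema["category"]: r.category,
                schema["basis"]: r.basis.value,
            }
            for name in MANDATORY_NUTRIENTS + ("fiber",):
                col = schema[name if name != "fiber" else "fiber"]
                row[col] = getattr(r, name)
            row[schema["ingredients_text"]] = r.ingredients_text
            rows.append(row)
        columns = [schema[f] for f in DEFAULT_SCHEMA]
        return pd.DataFrame(rows, columns=columns)


@dataclass
class ExclusionLog:
    """Which products were excluded, and under which (first-violated) rule."""

    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def counts_per_rule(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, rule in self.excluded:
            counts[rule] = counts.get(rule, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.excluded)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "excluded": [{"product_id": pid, "rule": rule} for pid, rule in self.excluded],
            "counts_per_rule": self.counts_per_rule,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def balanced_parentheses(text: str) -> bool:
    """True iff the count of '(' equals the count of ')' in ``text``.

    This is deliberately a count-equality check, not a nesting check: the
    cleaning criterion is that opening and closing parentheses are equal in
    number, so ``")("`` counts as balanced.
    """
    return text.count("(") == text.count(")")


def _parse_number(token: str, column: str, row: int, optional: bool) -> Optional[float]:
    token = token.strip()
    if token == "":
        return None
    try:
        value = float(token)
    except ValueError as exc:
        kind = "optional" if optional else "mandatory"
        raise RowParseError(
            f"row {row}: non-numeric value {token!r} in {kind} column {column!r}"
        ) from exc
    return value


def read_product_table(
    path: str | Path,
    schema: Optional[Mapping[str, str]] = None,
    provenance: str = "",
) -> ProductTable:
    """Read a product CSV into a :class:`ProductTable`.

    ``schema`` maps record fields to column names (defaults to
    :data:`DEFAULT_SCHEMA`).  Empty nutrient cells become absent values (not
    zero); a non-numeric token in a nutrient column raises
    :class:`RowParseError` with the offending data-row number (1-based).
    The ``basis``, ``fiber`` and ``ingredients_text`` columns are optional.
    """
    schema = dict(DEFAULT_SCHEMA if schema is None else schema)
    path = Path(path)
    df = pd.read_csv(path, dtype=str, comment="#", keep_default_na=False)

    required_fields = ("product_id", "brand", "category") + MANDATORY_NUTRIENTS
    for fld in required_fields:
        if schema[fld] not in df.columns:
            raise SchemaError(f"missing mandatory column {schema[fld]!r} (field {fld!r})")

    has_basis = schema["basis"] in df.columns
    has_fiber = schema["fiber"] in df.columns
    has_ingredients = schema["ingredients_text"] in df.columns

    records: list[ProductRecord] = []
    for i, raw in enumerate(df.to_dict(orient="records"), start=1):
        basis = Basis.PER_100G
        if has_basis and raw[schema["basis"]].strip():
            try:
                basis = Basis(raw[schema["basis"]].strip())
            except ValueError as exc:
                raise RowParseError(
                    f"row {i}: unknown basis {raw[schema['basis']]!r}"
                ) from exc
        nutrients = {
            name: _parse_number(raw[schema[name]], schema[name], i, optional=True)
            for name in MANDATORY_NUTRIENTS
        }
        fiber = (
            _parse_number(raw[schema["fiber"]], schema["fiber"], i, optional=True)
            if has_fiber
            else None
        )
        ingredients = raw[schema["ingredients_text"]] if has_ingredients else ""
        try:
            records.append(
                ProductRecord(
                    product_id=raw[schema["product_id"]].strip(),
                    brand=raw[schema["brand"]].strip(),
                    category=raw[schema["category"]].strip(),
                    basis=basis,
                    fiber=fiber,
                    ingredients_text=ingredients if ingredients != "" else None,
                    **nutrients,
                )
            )
        except ValueError as exc:
            raise RowParseError(f"row {i}: {exc}") from exc
    return ProductTable(records, provenance or path.name)


def write_product_table(
    table: ProductTable,
    path: str | Path,
    schema: Optional[Mapping[str, str]] = None,
    header_comment: Optional[str] = None,
) -> None:
    """Write a product CSV; ``header_comment`` lines are prefixed with '#'."""
    df = table.to_dataframe(schema)
    path = Path(path)
    with path.open("w", newline="") as handle:
        if header_comment:
            for line in header_comment.splitlines():
                handle.write(f"# {line}\n")
        df.to_csv(handle, index=False)


_RULE_DOC = {
    "missing_panel": "one or more of the six mandatory nutrients is absent",
    "missing_ingredients": "ingredients text absent or blank",
    "unbalanced_ingredients": "unequal counts of '(' and ')' in ingredients text",
    "missing_brand": "brand absent or blank",
    "duplicate_id": "product_id already seen earlier in the table",
}


def apply_exclusions(
    table: ProductTable,
    rules: Sequence[str] = EXCLUSION_RULES,
) -> tuple[ProductTable, ExclusionLog]:
    """Apply record-level exclusion rules in order; first violated rule wins.

    Returns the retained table (order preserved, records unmodified) and an
    :class:`ExclusionLog`.  ``rules`` must be drawn from
    :data:`EXCLUSION_RULES` and is applied in the order given.
    """
    unknown = [r for r in rules if r not in EXCLUSION_RULES]
    if unknown:
        raise ValueError(f"unknown exclusion rule(s): {unknown}; valid: {list(EXCLUSION_RULES)}")

    seen_ids: set[str] = set()
    retained: list[ProductRecord] = []
    log = ExclusionLog()
    for record in table.records:
        violated: Optional[str] = None
        for rule in rules:
            if rule == "missing_panel" and not record.has_panel():
                violated = rule
            elif rule == "missing_ingredients" and (
                record.ingredients_text is None or not record.ingredients_text.strip()
            ):
                violated = rule
            elif rule == "unbalanced_ingredients" and (
                record.ingredients_text is not None
                and not balanced_parentheses(record.ingredients_text)
            ):
                violated = rule
            elif rule == "missing_brand" and not record.brand.strip():
                violated = rule
            elif rule == "duplicate_id" and record.product_id in seen_ids:
                violated = rule
            if violated:
                break
        seen_ids.add(record.product_id)
        if violated:
            log.excluded.append((record.product_id, violated))
        else:
            retained.append(record)
    return ProductTable(retained, table.provenance), log


def filter_categories(
    table: ProductTable,
    min_reporting_rate: float = 0.25,
    allowed: Optional[Iterable[str]] = None,
) -> tuple[ProductTable, dict[str, str]]:
    """Drop categories below a fiber-reporting-rate threshold or off allow-list.

    The reporting rate of a category is the fraction of its records with a
    fiber value.  Retention at exactly the threshold is inclusive.  When an
    ``allowed`` list is given, categories outside it are dropped with reason
    ``"not_allowed"`` (checked before the rate).  Returns the retained table
    and a mapping of dropped category -> reason.
    """
    if len(table) == 0:
        raise ValueError("cannot filter categories of an empty table")
    if not 0 <= min_reporting_rate <= 1:
        raise ValueError(f"min_reporting_rate must be in [0, 1], got {min_reporting_rate}")
    allowed_set = set(allowed) if allowed is not None else None

    totals: dict[str, int] = {}
    reporting: dict[str, int] = {}
    for r in table.records:
        totals[r.category] = totals.get(r.category, 0) + 1
        if r.fiber is not None:
            reporting[r.category] = reporting.get(r.category, 0) + 1

    dropped: dict[str, str] = {}
    for cat, total in totals.items():
        if allowed_set is not None and cat not in allowed_set:
            dropped[cat] = "not_allowed"
            continue
        rate = reporting.get(cat, 0) / total
        if rate < min_reporting_rate:
            dropped[cat] = f"reporting_rate {rate:.4f} < {min_reporting_rate}"
    retained = ProductTable(
        [r for r in table.records if r.category not in dropped], table.provenance
    )
    if dropped:
        logger.info("filter_categories dropped %d categories: %s", len(dropped), dropped)
    return retained, dropped
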