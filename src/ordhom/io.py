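"""CSV readers/writers, subunit aggregation and schema configuration.

CSV is the canonical interchange.  An *area table* has one row per area with
an id column and n contiguous category columns (counts or proportions),
optionally a summary score and a population.  The column layout is supplied
through :class:`SchemaConfig` (or a small YAML file) rather than hard-coded
geography names, so the tooling is geography-agnostic.

A *subunit table* (subunit id, parent area id, category, population) can be
aggregated upward: per-area category counts are the sums of member subunit
populations, which is exactly the distributional input the indices need.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .distributions import (
    AreaRecord,
    DegenerateInputError,
    OrdinalDistribution,
    ValidationError,
)
from .location import location_index
from .homogeneity import classify_dataset
from .peergroups import IndicatorRecord

__all__ = [
    "SchemaConfig",
    "read_area_table",
    "write_area_table",
    "aggregate_subunits",
    "read_indicator_table",
    "classification_report",
    "write_classification_report",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SchemaConfig:
    """Column layout of an area table.

    Either list the category columns explicitly (in order) or give a
    ``category_prefix`` ("c" detects c1..cn).  ``proportion_atol`` is the
    tolerance on rows that hold proportions rather than counts; rows whose
    sum is within it of 1 are renormalised, anything else is an error.
    """

    id_column: str = "area_id"
    category_columns: Optional[tuple[str, ...]] = None
    category_prefix: str = "c"
    score_column: Optional[str] = None
    population_column: Optional[str] = None
    proportion_atol: float = 1e-2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SchemaConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "category_columns" in raw and raw["category_columns"] is not None:
            raw["category_columns"] = tuple(raw["category_columns"])
        return cls(**raw)

    def resolve_categories(self, columns: Sequence[str]) -> list[str]:
        if self.category_columns:
            missing = [c for c in self.category_columns if c not in columns]
            if missing:
                raise ValidationError(f"category columns not in file: {missing}")
            return list(self.category_columns)
        found = [c for c in columns if _is_prefixed(c, self.category_prefix)]
        found.sort(key=lambda c: int(c[len(self.category_prefix):]))
        if len(found) < 3:
            raise ValidationError(
                f"found {len(found)} category columns with prefix "
                f"{self.category_prefix!r}; need at least 3"
            )
        return found


def _is_prefixed(col: str, prefix: str) -> bool:
    return col.startswith(prefix) and col[len(prefix):].isdigit()


def read_area_table(
    path: str | Path, schema: SchemaConfig | None = None
) -> list[AreaRecord]:
    """Read an area table; counts are normalised to proportions.

    Malformed rows are reported together, each with its 1-based data row
    number.  Rows of proportions summing within ``schema.proportion_atol``
    of 1 are accepted and renormalised.
    """
    schema = schema or SchemaConfig()
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValidationError(f"{path}: no data rows")
    if schema.id_column not in df.columns:
        raise ValidationError(f"{path}: missing id column {schema.id_column!r}")
    cats = schema.resolve_categories(df.columns)
    records: list[AreaRecord] = []
    errors: list[str] = []
    for row_no, (_, row) in enumerate(df.iterrows(), start=1):
        area_id = str(row[schema.id_column])
        try:
            values = pd.to_numeric(row[cats], errors="raise").to_numpy(float)
        except (ValueError, TypeError):
            errors.append(f"row {row_no} ({area_id}): non-numeric category cell")
            continue
        try:
            dist = _row_to_distribution(values, schema)
            score = None
            if schema.score_column and schema.score_column in df.columns:
                score = float(row[schema.score_column])
            if schema.population_column and schema.population_column in df.columns:
                dist = OrdinalDistribution(
                    dist.proportions, population=float(row[schema.population_column])
                )
            records.append(AreaRecord(area_id=area_id, distribution=dist, score=score))
        except (ValidationError, DegenerateInputError) as exc:
            errors.append(f"row {row_no} ({area_id}): {exc}")
    if errors:
        raise ValidationError(f"{path}: " + "; ".join(errors))
    return records


def _row_to_distribution(values: np.ndarray, schema: SchemaConfig) -> OrdinalDistribution:
    if np.any(~np.isfinite(values)):
        raise ValidationError("missing category value")
    if np.any(values < 0):
        raise ValidationError("negative category value")
    total = values.sum()
    if total <= 0:
        raise DegenerateInputError("all-zero category values")
    if abs(total - 1.0) <= schema.proportion_atol:
        # proportions within tolerance: renormalise
        return OrdinalDistribution(values / total)
    # otherwise treat as counts
    return OrdinalDistribution(values / total, population=float(total))


def write_area_table(
    areas: Sequence[AreaRecord], path: str | Path, schema: SchemaConfig | None = None
) -> None:
    """Write areas as proportions in the same dialect ``read_area_table`` reads."""
    schema = schema or SchemaConfig()
    rows = []
    for a in areas:
        n = a.distribution.n
        cats = (
            list(schema.category_columns)
            if schema.category_columns
            else [f"{schema.category_prefix}{i}" for i in range(1, n + 1)]
        )
        row = {schema.id_column: a.area_id}
        row.update(zip(cats, a.distribution.proportions))
        if a.distribution.population is not None:
            row[schema.population_column or "population"] = a.distribution.population
        if a.score is not None:
            row[schema.score_column or "score"] = a.score
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def aggregate_subunits(
    subunits: pd.DataFrame, n_categories: Optional[int] = None
) -> list[AreaRecord]:
    """Aggregate a subunit table to per-area distributions.

    Expects columns subunit_id, area_id, category (1-based), population.
    Category counts are sums of member subunit populations; row order does
    not matter and the total population is conserved exactly.
    """
    required = {"area_id", "category", "population"}
    missing = required - set(subunits.columns)
    if missing:
        raise ValidationError(f"subunit table missing columns: {sorted(missing)}")
    if subunits.empty:
        raise ValidationError("subunit table is empty")
    cat = subunits["category"].to_numpy()
    pop = subunits["population"].to_numpy(float)
    if np.any(pop < 0):
        raise ValidationError("subunit populations must be nonnegative")
    n = int(n_categories or cat.max())
    if cat.min() < 1 or cat.max() > n:
        raise ValidationError(f"categories must lie in 1..{n}")
    records = []
    for area_id in sorted(subunits["area_id"].unique(), key=str):
        sel = subunits["area_id"] == area_id
        counts = np.bincount(cat[sel] - 1, weights=pop[sel], minlength=n)
        total = counts.sum()
        if total <= 0:
            raise DegenerateInputError(f"area {area_id!r} has zero total population")
        records.append(
            AreaRecord(
                area_id=str(area_id),
                distribution=OrdinalDistribution(counts / total, population=float(total)),
            )
        )
    return records


def read_indicator_table(path: str | Path) -> list[IndicatorRecord]:
    """Read (area_id, rate) rows."""
    df = pd.read_csv(path)
    for col in ("area_id", "rate"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return [
        IndicatorRecord(area_id=str(r.area_id), rate=float(r.rate))
        for r in df.itertuples()
    ]


def classification_report(areas: Sequence[AreaRecord]) -> pd.DataFrame:
    """Classification table with Location Index and band, rounded for
    reporting (HI to 2 decimals, true diversity to 1)."""
    from .peergroups import disadvantage_band  # local import to avoid cycle

    result = classify_dataset(areas)
    table = result.table.copy()
    lis = {}
    for a in areas:
        lis[a.area_id] = location_index(a.distribution).li
    table["li"] = pd.Series(lis)
    table["band"] = [
        disadvantage_band(li, a.distribution.n) for li, a in zip(table["li"], areas)
    ]
    table["hi"] = table["hi"].round(2)
    table["s"] = table["s"].round(1)
    table["ci"] = table["ci"].round(4)
    table["di"] = table["di"].round(4)
    return table


def write_classification_report(areas: Sequence[AreaRecord], path: str | Path) -> pd.DataFrame:
    report = classification_report(areas)
    report.to_csv(path)
    log.info("wrote classification report for %d areas to %s", len(report), path)
    return report
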