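"""Constraint-table schema and aggregate harmonisation.

Small-area aggregate statistics arrive as one count table per constraint
characteristic (age-and-sex, marital status, household size, economic
status, education).  Different census questions cover different subsets of
the population — optional questions, communal housing, absent residents —
so the raw tables of one area rarely share a total.  Synthesis methods such
as iterative proportional fitting require every constraint table to sum to
one common target population, so this module harmonises them:

* detailed source categories are merged to match the survey's coding,
* single-year age counts are combined into five-year groups,
* optional-question tables are padded with an explicit ``<table>_NA``
  category for the people the question does not apply to,
* remaining tables are rescaled to the target total with an integer
  largest-remainder sweep (a Bresenham-style error accumulator) that keeps
  every cell within one person of its exact proportional share,
* areas published under a duplicated identifier are summed.

The target population of an area is defined as the total of the table whose
role is "persons usually resident" (household size, ``T5_2``, in the default
schema).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SchemaError",
    "DataError",
    "RescaleRequired",
    "CategorySchema",
    "RawAreaTable",
    "AreaConstraints",
    "merge_detailed_categories",
    "combine_age_years",
    "pad_with_na",
    "rescale_to_total",
    "merge_duplicate_areas",
    "harmonise_area",
]


class SchemaError(ValueError):
    """A table, category or merge map is inconsistent with the schema."""


class DataError(ValueError):
    """Counts violate a data invariant (negative, missing, undefined)."""


class RescaleRequired(DataError):
    """NA padding was requested for a table whose total already exceeds the
    target population; rescaling is the applicable operation instead."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CategorySchema:
    """The universe of constraint tables and their ordered category codes.

    Parameters
    ----------
    tables:
        Ordered ``(table_name, category codes)`` pairs.  Category order is
        significant: it fixes the traversal order of the deterministic
        rescaling sweep and the cell order of concatenated count vectors.
    sexed:
        Names of tables whose categories are split by sex.
    optional:
        Tables backed by optional (or restricted-applicability) questions.
        When such a table undercounts the target population the shortfall is
        booked to its ``<table>_NA`` category instead of rescaling up.
    resident_table:
        The table whose total defines an area's target population
        (``target_n``); conventionally the household-size table, whose
        universe is "persons usually resident in private households".
    """

    tables: tuple[tuple[str, tuple[str, ...]], ...]
    sexed: frozenset[str] = frozenset()
    optional: frozenset[str] = frozenset()
    resident_table: str | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        names: set[str] = set()
        for name, cats in self.tables:
            if name in names:
                raise SchemaError(f"duplicate table name {name!r}")
            names.add(name)
            if len(cats) < 2:
                raise SchemaError(f"table {name!r} has fewer than 2 categories")
            for code in cats:
                if code in seen:
                    raise SchemaError(f"category code {code!r} is not unique")
                seen.add(code)
        if self.resident_table is not None and self.resident_table not in names:
            raise SchemaError(
                f"resident table {self.resident_table!r} not in schema"
            )
        for name in self.sexed | self.optional:
            if name not in names:
                raise SchemaError(f"flagged table {name!r} not in schema")

    # -- lookups ------------------------------------------------------------

    @property
    def table_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.tables)

    def categories(self, table: str) -> tuple[str, ...]:
        for name, cats in self.tables:
            if name == table:
                return cats
        raise SchemaError(f"unknown table {table!r}")

    def na_code(self, table: str) -> str:
        return f"{table}_NA"

    def category_index(self, table: str) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.categories(table))}

    @property
    def n_cells(self) -> int:
        return sum(len(cats) for _, cats in self.tables)

    def to_dict(self) -> dict:
        return {
            "tables": [
                {"name": name, "categories": list(cats)}
                for name, cats in self.tables
            ],
            "sexed": sorted(self.sexed),
            "optional": sorted(self.optional),
            "resident_table": self.resident_table,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CategorySchema":
        return cls(
            tables=tuple(
                (t["name"], tuple(t["categories"])) for t in d["tables"]
            ),
            sexed=frozenset(d.get("sexed", ())),
            optional=frozenset(d.get("optional", ())),
            resident_table=d.get("resident_table"),
        )


@dataclass
class RawAreaTable:
    """One area's raw counts for one constraint table (pre-harmonisation)."""

    area_id: str
    table_name: str
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class AreaConstraints:
    """Harmonised marginal counts for one area; all tables sum to target_n."""

    area_id: str
    target_n: int
    tables: dict[str, dict[str, int]]

    def counts_vector(self, schema: CategorySchema, table: str) -> np.ndarray:
        cats = schema.categories(table)
        tbl = self.tables[table]
        return np.array([tbl.get(c, 0) for c in cats], dtype=np.int64)

    def concatenated(self, schema: CategorySchema) -> np.ndarray:
        """All tables' counts as one vector in schema cell order."""
        return np.concatenate(
            [self.counts_vector(schema, t) for t in schema.table_names]
        )

    def validate(self, schema: CategorySchema) -> None:
        for name in schema.table_names:
            if name not in self.tables:
                raise SchemaError(f"area {self.area_id}: missing table {name}")
            vec = self.counts_vector(schema, name)
            if vec.min() < 0:
                raise DataError(f"negative count in {name}")
            if vec.sum() != self.target_n:
                raise DataError(
                    f"area {self.area_id}: table {name} sums to "
                    f"{int(vec.sum())}, expected {self.target_n}"
                )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def merge_detailed_categories(
    raw: RawAreaTable, merge_map: Mapping[str, Sequence[str]]
) -> RawAreaTable:
    """Sum groups of detailed source categories into coarser survey ones.

    Census aggregates often split what a survey codes as one category
    (separated vs divorced; three kinds of unemployment).  ``merge_map``
    sends each new code to the list of old codes it absorbs; codes not
    mentioned pass through unchanged.  Totals are conserved.
    """
    owner: dict[str, str] = {}
    for new_code, old_codes in merge_map.items():
        for old in old_codes:
            if old in owner:
                raise SchemaError(
                    f"category {old!r} appears in merge groups "
                    f"{owner[old]!r} and {new_code!r}"
                )
            if old not in raw.counts:
                raise SchemaError(
                    f"merge source {old!r} not present in table "
                    f"{raw.table_name!r}"
                )
            owner[old] = new_code

    merged: dict[str, int] = {}
    for code, count in raw.counts.items():
        if code not in owner:
            merged[code] = merged.get(code, 0) + count
    for new_code, old_codes in merge_map.items():
        merged[new_code] = merged.get(new_code, 0) + sum(
            raw.counts[old] for old in old_codes
        )
    return RawAreaTable(raw.area_id, raw.table_name, merged)


def combine_age_years(
    raw_single_year_counts: Mapping[int, int], bin_width: int = 5
) -> dict[str, int]:
    """Combine single-year-of-age counts into ``AGE<lo>_<hi>`` groups.

    Census aggregates give ages 0–19 per single year while adult ages are
    already grouped; this regroups the single years into the same
    ``bin_width``-year bands (default 5).
    """
    if bin_width < 1:
        raise DataError("bin_width must be >= 1")
    out: dict[str, int] = {}
    for age in sorted(raw_single_year_counts):
        count = raw_single_year_counts[age]
        if age < 0:
            raise DataError(f"negative age {age}")
        if count < 0:
            raise DataError(f"negative count for age {age}")
        lo = (age // bin_width) * bin_width
        code = f"AGE{lo}_{lo + bin_width - 1}"
        out[code] = out.get(code, 0) + count
    return out


def pad_with_na(raw: RawAreaTable, target_n: int) -> RawAreaTable:
    """Book the shortfall to an explicit ``<table>_NA`` category.

    Used for tables from optional or restricted questions (education is not
    asked of children or students, economic status not of children): the
    people the question does not apply to become an explicit
    "not applicable" category so the table totals ``target_n``.
    """
    total = raw.total
    if total > target_n:
        raise RescaleRequired(
            f"table {raw.table_name!r} total {total} exceeds target "
            f"{target_n}; rescale instead of padding"
        )
    na = f"{raw.table_name}_NA"
    counts = dict(raw.counts)
    counts[na] = counts.get(na, 0) + (target_n - total)
    return RawAreaTable(raw.area_id, raw.table_name, counts)


def rescale_to_total(
    counts: Sequence[int], target_total: int
) -> list[int]:
    """Integer-rescale counts to a new total, largest-remainder style.

    Deterministic error-accumulator sweep in input order (the integer
    analogue of Bresenham's line algorithm): each output cell equals the
    floor of its exact proportional share, and the leftover units go to the
    cells with the largest fractional remainders, ties broken by first
    index.  Guarantees ``sum(out) == target_total`` and
    ``|out[i] - share[i]| < 1`` for every cell.  All arithmetic is exact
    integer arithmetic.
    """
    counts = [int(c) for c in counts]
    if any(c < 0 for c in counts):
        raise DataError("negative count")
    total = sum(counts)
    if target_total < 0:
        raise DataError("negative target total")
    if total == target_total:
        return list(counts)
    if total == 0:
        if target_total == 0:
            return [0] * len(counts)
        raise DataError(
            "cannot rescale an all-zero table to a positive total"
        )
    # exact share of cell i is counts[i] * target_total / total
    base = [c * target_total // total for c in counts]
    frac = [c * target_total % total for c in counts]  # numerators over total
    remainder = target_total - sum(base)
    order = sorted(range(len(counts)), key=lambda i: (-frac[i], i))
    out = list(base)
    for i in order[:remainder]:
        out[i] += 1
    return out


def merge_duplicate_areas(tables: Sequence[RawAreaTable]) -> RawAreaTable:
    """Element-wise sum of tables published under one shared area id."""
    if not tables:
        raise SchemaError("no tables to merge")
    first = tables[0]
    counts: dict[str, int] = {}
    for t in tables:
        if t.table_name != first.table_name:
            raise SchemaError(
                f"cannot merge tables {first.table_name!r} and "
                f"{t.table_name!r}"
            )
        if t.area_id != first.area_id:
            raise SchemaError(
                f"cannot merge area {first.area_id!r} with {t.area_id!r}"
            )
        for code, c in t.counts.items():
            counts[code] = counts.get(code, 0) + c
    return RawAreaTable(first.area_id, first.table_name, counts)


def harmonise_area(
    raw_tables: Iterable[RawAreaTable],
    schema: CategorySchema,
    *,
    pad_mandatory: bool = False,
) -> AreaConstraints:
    """Harmonise one area's raw tables into consistent constraints.

    The total of the resident-role table defines ``target_n``.  Every other
    table is brought to that total: optional-question tables falling short
    are NA-padded; all other mismatches are rescaled (up or down) with
    :func:`rescale_to_total`.  ``pad_mandatory=True`` extends NA padding to
    undercounting mandatory tables as well.

    Idempotent: harmonising an already-consistent area returns it unchanged.
    """
    if schema.resident_table is None:
        raise SchemaError("schema declares no resident (target-defining) table")

    grouped: dict[str, list[RawAreaTable]] = {}
    area_ids = set()
    for t in raw_tables:
        grouped.setdefault(t.table_name, []).append(t)
        area_ids.add(t.area_id)
    if len(area_ids) != 1:
        raise SchemaError(f"tables span multiple areas: {sorted(area_ids)}")
    area_id = area_ids.pop()

    merged = {
        name: merge_duplicate_areas(ts) if len(ts) > 1 else ts[0]
        for name, ts in grouped.items()
    }
    if schema.resident_table not in merged:
        raise SchemaError(
            f"area {area_id}: resident table {schema.resident_table!r} "
            "missing; cannot define target_n"
        )
    target_n = merged[schema.resident_table].total

    out: dict[str, dict[str, int]] = {}
    for name in schema.table_names:
        if name not in merged:
            raise SchemaError(f"area {area_id}: missing table {name!r}")
        raw = merged[name]
        cats = schema.categories(name)
        unknown = set(raw.counts) - set(cats)
        if unknown:
            raise SchemaError(
                f"area {area_id}: table {name!r} has codes outside the "
                f"schema: {sorted(unknown)}"
            )
        if any(c < 0 for c in raw.counts.values()):
            raise DataError(f"area {area_id}: negative count in {name!r}")
        total = raw.total
        if total < target_n and (name in schema.optional or pad_mandatory):
            if schema.na_code(name) not in cats:
                raise SchemaError(
                    f"table {name!r} needs NA padding but the schema has no "
                    f"{schema.na_code(name)!r} category"
                )
            raw = pad_with_na(raw, target_n)
            total = target_n
        if total != target_n:
            vec = [raw.counts.get(c, 0) for c in cats]
            scaled = rescale_to_total(vec, target_n)
            out[name] = dict(zip(cats, scaled))
        else:
            out[name] = {c: raw.counts.get(c, 0) for c in cats}

    result = AreaConstraints(area_id=area_id, target_n=target_n, tables=out)
    result.validate(schema)
    return result
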