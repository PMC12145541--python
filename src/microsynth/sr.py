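"""Synthetic reconstruction: person-by-person conditional sampling.

Each synthetic person is built one characteristic at a time.  The first
characteristic is drawn from the target area's marginal for that table
(by default depleting it without replacement, which makes the first table
fit exactly); every later characteristic is drawn from the survey's
conditional distribution given the categories already assigned, e.g.
P(house size | retired, married, aged 70-74, postgraduate, female).

Because a finite survey cannot populate every conditioning cell, an
empty-cell fallback is part of the sampling contract: when no survey
record matches the current conditions, the most recently added condition
is dropped and the lookup retried, recursing to the unconditional marginal
if necessary.  The result is therefore always a valid distribution.

The order in which characteristics are sampled may be fixed, or adaptive:
at each person the table whose running synthetic proportions deviate most
from the area's target proportions (max absolute difference) is sampled
first, letting a drifting characteristic re-align.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fixtures import (
    ContingencyTensor,
    MicrodataSample,
    PersonRecord,
    SyntheticPopulation,
    cross_tabulate,
)
from .schema import AreaConstraints, CategorySchema, DataError, SchemaError

__all__ = [
    "ConditionalQuery",
    "SRPolicy",
    "conditional_distribution",
    "ConditionalModel",
    "synthesize_person",
    "synthesize_population_sr",
]


@dataclass(frozen=True)
class ConditionalQuery:
    """Ask for P(target_table | fixed categories), in conditioning order."""

    fixed: tuple[tuple[str, str], ...]  # (table, category), oldest first
    target_table: str

    def __post_init__(self) -> None:
        if self.target_table in {t for t, _ in self.fixed}:
            raise SchemaError("target_table cannot also be conditioned on")


@dataclass
class SRPolicy:
    """Sampling-order policy.

    ``base_order`` is a permutation of the schema tables (default: schema
    order).  With ``reorder='fixed'`` the first table of ``base_order`` is
    always drawn from the area marginal; with ``'adaptive'`` the table with
    the largest current proportional deviation is drawn first instead, ties
    broken by ``base_order`` position.  ``first_draw`` selects depletion
    (without-replacement, exact first-table fit) or with-replacement
    Monte-Carlo draws from the target proportions.
    """

    base_order: tuple[str, ...] | None = None
    reorder: str = "fixed"  # "fixed" | "adaptive"
    first_draw: str = "deplete"  # "deplete" | "replace"

    def __post_init__(self) -> None:
        if self.reorder not in ("fixed", "adaptive"):
            raise SchemaError(f"unknown reorder rule {self.reorder!r}")
        if self.first_draw not in ("deplete", "replace"):
            raise SchemaError(f"unknown first_draw mode {self.first_draw!r}")

    def resolved_order(self, schema: CategorySchema) -> tuple[str, ...]:
        order = self.base_order or schema.table_names
        if sorted(order) != sorted(schema.table_names):
            raise SchemaError(
                "base_order must be a permutation of the schema tables"
            )
        return tuple(order)


def conditional_distribution(
    sample: MicrodataSample,
    query: ConditionalQuery,
    schema: CategorySchema,
) -> np.ndarray:
    """Survey conditional distribution of the target table's categories.

    Straightforward filter-and-count over the survey records, with the
    drop-last-condition fallback when no record matches.  For bulk
    synthesis use :class:`ConditionalModel`, which computes the same
    quantity from a precomputed cross-tabulation.
    """
    if not sample.persons:
        raise DataError("empty microdata sample")
    cats = schema.categories(query.target_table)
    index = {c: i for i, c in enumerate(cats)}
    fixed = list(query.fixed)
    while True:
        counts = np.zeros(len(cats))
        for p in sample.persons:
            if all(p.categories.get(t) == c for t, c in fixed):
                counts[index[p.categories[query.target_table]]] += 1
        total = counts.sum()
        if total > 0:
            return counts / total
        if not fixed:
            raise DataError(
                f"no record carries any category of {query.target_table}"
            )
        fixed.pop()  # drop the most recently added condition and retry


class ConditionalModel:
    """Conditional distributions served from the survey cross-tabulation.

    Mathematically identical to :func:`conditional_distribution` (the
    tensor cell counts are exactly the filter-and-count results) but each
    lookup is a tensor slice-and-sum, which makes whole-population
    synthesis tractable.
    """

    def __init__(self, sample: MicrodataSample, schema: CategorySchema):
        if not sample.persons:
            raise DataError("empty microdata sample")
        self.schema = schema
        self.tensor: ContingencyTensor = cross_tabulate(sample.persons, schema)
        self._axis = {t: i for i, t in enumerate(self.tensor.dims)}
        self._cat_index = {
            t: schema.category_index(t) for t in schema.table_names
        }

    def distribution(
        self, fixed: Sequence[tuple[str, str]], target_table: str
    ) -> np.ndarray:
        target_ax = self._axis[target_table]
        fixed = list(fixed)
        while True:
            view = self.tensor.values
            # fix conditioned axes one at a time (later axes shift left)
            axes = sorted(
                (self._axis[t], self._cat_index[t][c]) for t, c in fixed
            )
            t_ax = target_ax
            for shift, (ax, ci) in enumerate(axes):
                view = np.take(view, ci, axis=ax - shift)
                if ax < target_ax:
                    t_ax -= 1
            other = tuple(i for i in range(view.ndim) if i != t_ax)
            counts = view.sum(axis=other) if other else view
            total = counts.sum()
            if total > 0:
                return counts / total
            if not fixed:
                raise DataError(
                    f"no record carries any category of {target_table}"
                )
            fixed.pop()

    def query(self, q: ConditionalQuery) -> np.ndarray:
        return self.distribution(q.fixed, q.target_table)


def _deviation(
    running: dict[str, np.ndarray],
    constraints: AreaConstraints,
    schema: CategorySchema,
    n_done: int,
) -> dict[str, float]:
    """Max absolute difference between running and target proportions."""
    out = {}
    for t in schema.table_names:
        target = constraints.counts_vector(schema, t)
        p_target = target / max(constraints.target_n, 1)
        p_cur = running[t] / n_done if n_done > 0 else np.zeros_like(p_target)
        out[t] = float(np.abs(p_cur - p_target).max())
    return out


def _choose_first_table(
    policy: SRPolicy,
    schema: CategorySchema,
    running: dict[str, np.ndarray],
    constraints: AreaConstraints,
    n_done: int,
) -> str:
    order = policy.resolved_order(schema)
    if policy.reorder == "fixed":
        return order[0]
    dev = _deviation(running, constraints, schema, n_done)
    return max(order, key=lambda t: (dev[t], -order.index(t)))


def synthesize_person(
    constraints: AreaConstraints,
    running_counts: dict[str, np.ndarray],
    model: ConditionalModel,
    policy: SRPolicy,
    rng: np.random.Generator,
    person_id: str = "SR0",
) -> PersonRecord:
    """Build one person: area marginal first, survey conditionals after."""
    schema = model.schema
    n_done = int(running_counts[schema.table_names[0]].sum())
    if n_done >= constraints.target_n:
        raise DataError("population already at target size")

    first = _choose_first_table(policy, schema, running_counts, constraints, n_done)
    target = constraints.counts_vector(schema, first).astype(float)
    if policy.first_draw == "deplete":
        # categories overfilled by conditional draws of other steps are
        # clamped to zero demand; the total remaining is target_n - n_done > 0
        remaining = np.maximum(target - running_counts[first], 0.0)
        if remaining.sum() <= 0:
            raise DataError(
                f"marginal of {first} exhausted with demand remaining"
            )
        probs = remaining / remaining.sum()
    else:
        probs = target / target.sum()
    cats_first = schema.categories(first)
    ci = int(rng.choice(len(cats_first), p=probs))
    fixed: list[tuple[str, str]] = [(first, cats_first[ci])]

    order = policy.resolved_order(schema)
    for table in order:
        if table == first:
            continue
        probs = model.distribution(fixed, table)
        cats = schema.categories(table)
        ci = int(rng.choice(len(cats), p=probs))
        fixed.append((table, cats[ci]))

    categories = dict(fixed)
    return PersonRecord(
        person_id=person_id, household_id=person_id, categories=categories
    )


def synthesize_population_sr(
    constraints: AreaConstraints,
    sample: MicrodataSample,
    policy: SRPolicy | None = None,
    rng: np.random.Generator | int | None = None,
    schema: CategorySchema | None = None,
) -> SyntheticPopulation:
    """Synthesise a full area population of exactly ``target_n`` persons."""
    policy = policy or SRPolicy()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if schema is None:
        from .fixtures import default_schema

        schema = default_schema()
    model = ConditionalModel(sample, schema)
    running = {
        t: np.zeros(len(schema.categories(t))) for t in schema.table_names
    }
    idx_maps = {t: schema.category_index(t) for t in schema.table_names}
    persons: list[PersonRecord] = []
    for i in range(constraints.target_n):
        p = synthesize_person(
            constraints,
            running,
            model,
            policy,
            rng,
            person_id=f"{constraints.area_id}_sr_{i:06d}",
        )
        for t, code in p.categories.items():
            running[t][idx_maps[t][code]] += 1
        persons.append(p)
    return SyntheticPopulation(
        area_id=constraints.area_id, persons=persons, method="sr"
    )
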