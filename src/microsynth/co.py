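"""Combinatorial optimisation: selecting real survey units for an area.

Simulated annealing and a genetic algorithm both search for a subset
(with replacement) of survey households — or individual persons — whose
tabulated characteristics match an area's constraint tables.  Both share
one fitness contract: total absolute error (TAE), the sum over every
constraint-table cell of |tabulated − target|.  TAE is zero exactly when
every table matches, integer-valued, and cheap to update incrementally.

Simulated annealing perturbs a single candidate by swapping a
temperature-dictated number of units for fresh random draws; worsening
swaps are accepted with probability exp(−ΔE / kT), and the temperature is
multiplied by the cooling factor (default 0.85) every iteration.  The
genetic algorithm evolves a population of candidates through
with-replacement tournaments, unit-exchange crossover and random-replacement
mutation, children replacing parents each generation; the best candidate
ever seen is returned.  A uniform random household draw provides the
baseline both are judged against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .fixtures import (
    MicrodataSample,
    PersonRecord,
    SyntheticPopulation,
    tally,
)
from .schema import AreaConstraints, CategorySchema, DataError

__all__ = [
    "Candidate",
    "SAConfig",
    "GAConfig",
    "fitness",
    "acceptance_probability",
    "simulated_annealing",
    "tournament_select",
    "crossover",
    "mutate",
    "genetic_algorithm",
    "random_baseline",
]


@dataclass
class Candidate:
    """A proposed area population: a multiset of survey units."""

    units: list  # HouseholdRecord (household mode) or PersonRecord
    unit_kind: str = "household"  # "household" | "person"

    def persons(self) -> list[PersonRecord]:
        if self.unit_kind == "household":
            return [p for h in self.units for p in h.members]
        return list(self.units)


@dataclass
class SAConfig:
    """Simulated-annealing controls.

    The temperature after ``i`` iterations is ``initial * 0.85**i``; the
    number of units proposed for swapping at temperature T is
    ``max(1, ceil(T/T0 * current unit count))``.  ``initial_temperature``
    defaults to ``0.1 * initial unit count`` when left unset.  The run
    stops at ``fitness <= fitness_threshold`` (default 0, a perfect fit)
    or after ``max_iter`` iterations.
    """

    initial_temperature: float | None = None
    cooling_factor: float = 0.85
    k: float = 1.0
    fitness_threshold: float = 0.0
    max_iter: int = 100000

    def __post_init__(self) -> None:
        if not (0.0 < self.cooling_factor < 1.0):
            raise DataError("cooling_factor must be in (0, 1)")
        if self.k <= 0:
            raise DataError("k must be positive")

    def temperature(self, i: int, t0: float) -> float:
        """Temperature after ``i`` iterations of cooling."""
        return t0 * self.cooling_factor**i


@dataclass
class GAConfig:
    population_count: int = 100
    generations: int = 500
    tournament_size: int = 10
    crossover_rate: float = 0.7
    mutation_rate: float = 0.05
    elitism: bool = False

    def __post_init__(self) -> None:
        if self.tournament_size > self.population_count:
            raise DataError("tournament_size cannot exceed population_count")
        if self.tournament_size < 1:
            raise DataError("tournament_size must be >= 1")
        for r in (self.crossover_rate, self.mutation_rate):
            if not (0.0 <= r <= 1.0):
                raise DataError("rates must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------------


def fitness(
    candidate: Candidate,
    constraints: AreaConstraints,
    schema: CategorySchema,
) -> int:
    """Total absolute error of the candidate against the constraints."""
    counts = tally(candidate.persons(), schema)
    tae = 0
    for t in schema.table_names:
        target = constraints.counts_vector(schema, t)
        tae += int(np.abs(counts[t] - target).sum())
    return tae


def acceptance_probability(delta_e: float, temperature: float, k: float = 1.0) -> float:
    """Metropolis acceptance: exp(−ΔE/kT), 1 for non-worsening moves."""
    if temperature <= 0:
        raise DataError("temperature must be positive")
    if k <= 0:
        raise DataError("k must be positive")
    if delta_e <= 0:
        return 1.0
    return min(1.0, math.exp(-delta_e / (k * temperature)))


# ---------------------------------------------------------------------------
# Internal vectorised search state
# ---------------------------------------------------------------------------


class _UnitSpace:
    """Survey units as count vectors over the concatenated constraint cells."""

    def __init__(
        self,
        sample: MicrodataSample,
        schema: CategorySchema,
        unit_kind: str,
    ):
        if unit_kind not in ("household", "person"):
            raise DataError(f"unknown unit_kind {unit_kind!r}")
        if not sample.persons:
            raise DataError("empty microdata sample")
        self.schema = schema
        self.unit_kind = unit_kind
        self.units: Sequence = (
            sample.households if unit_kind == "household" else sample.persons
        )
        offsets = {}
        off = 0
        for t in schema.table_names:
            offsets[t] = off
            off += len(schema.categories(t))
        self.n_cells = off
        idx_maps = {t: schema.category_index(t) for t in schema.table_names}

        def person_cells(p: PersonRecord) -> list[int]:
            return [
                offsets[t] + idx_maps[t][p.categories[t]]
                for t in schema.table_names
            ]

        mat = np.zeros((len(self.units), off), dtype=np.int32)
        sizes = np.zeros(len(self.units), dtype=np.int64)
        for i, u in enumerate(self.units):
            members = u.members if unit_kind == "household" else [u]
            sizes[i] = len(members)
            for p in members:
                for c in person_cells(p):
                    mat[i, c] += 1
        self.matrix = mat
        self.sizes = sizes
        self._sizes_list = sizes.tolist()
        self._mean_size = max(1, int(sizes.mean()))
        self.max_size = int(sizes.max())

    def counts(self, idx: Sequence[int]) -> np.ndarray:
        return self.matrix[list(idx)].sum(axis=0, dtype=np.int64)

    def random_units(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.integers(0, len(self.units), size=n)

    def initial_candidate(
        self, target_n: int, rng: np.random.Generator
    ) -> list[int]:
        """Random units until the person total reaches the target."""
        if self.unit_kind == "person":
            return list(self.random_units(target_n, rng))
        idx: list[int] = []
        total = 0
        sizes = self._sizes_list
        while total < target_n:
            k = max(1, (target_n - total) // self._mean_size)
            for u in self.random_units(k, rng):
                u = int(u)
                idx.append(u)
                total += sizes[u]
                if total >= target_n:
                    break
        return idx

    def repair_tracked(
        self,
        idx: list[int],
        target_n: int,
        rng: np.random.Generator,
        total: int | None = None,
    ) -> tuple[list[int], list[int], list[int]]:
        """Restore the household-mode size band after unit replacement.

        Adds random households while the person total is short of the
        target, then removes (in random order) any household whose removal
        keeps the total at or above the target, so the overshoot stays
        below the largest household size.  Returns the repaired list and
        the units added and removed (for incremental count updates).
        """
        if self.unit_kind == "person":
            return idx, [], []
        sizes = self._sizes_list
        if total is None:
            total = sum(sizes[u] for u in idx)
        if target_n <= total < target_n + self.max_size:
            return idx, [], []
        added: list[int] = []
        removed: list[int] = []
        while total < target_n:
            k = max(1, (target_n - total) // self._mean_size)
            for u in self.random_units(k, rng):
                u = int(u)
                idx.append(u)
                added.append(u)
                total += sizes[u]
                if total >= target_n:
                    break
        order = rng.permutation(len(idx))
        keep = np.ones(len(idx), dtype=bool)
        for j in order:
            s = sizes[idx[j]]
            if total - s >= target_n:
                keep[j] = False
                removed.append(idx[j])
                total -= s
        if removed:
            idx = [u for u, k in zip(idx, keep) if k]
        return idx, added, removed

    def repair(
        self, idx: list[int], target_n: int, rng: np.random.Generator
    ) -> list[int]:
        return self.repair_tracked(idx, target_n, rng)[0]

    def counts_batch(self, candidates: Sequence[Sequence[int]]) -> np.ndarray:
        """Count vectors of many candidates in one pass.

        Builds the candidate-by-unit multiplicity matrix and multiplies it
        with the unit-by-cell matrix in float32 (exact for these magnitudes).
        """
        lengths = np.fromiter((len(c) for c in candidates), dtype=np.intp)
        flat = np.concatenate([np.asarray(c, dtype=np.intp) for c in candidates])
        seg = np.repeat(np.arange(len(candidates)), lengths)
        mult = np.zeros((len(candidates), len(self.units)), dtype=np.float32)
        np.add.at(mult, (seg, flat), 1.0)
        if not hasattr(self, "_matrix_f32"):
            self._matrix_f32 = self.matrix.astype(np.float32)
        return (mult @ self._matrix_f32).astype(np.int64)

    def to_population(
        self, idx: Sequence[int], area_id: str, method: str
    ) -> SyntheticPopulation:
        persons: list[PersonRecord] = []
        i = 0
        for u in idx:
            members = (
                self.units[u].members
                if self.unit_kind == "household"
                else [self.units[u]]
            )
            hh = f"{area_id}_{method}_h{i:06d}"
            for p in members:
                persons.append(
                    PersonRecord(
                        person_id=f"{area_id}_{method}_{len(persons):06d}",
                        household_id=hh if self.unit_kind == "household" else f"{area_id}_{method}_h{len(persons):06d}",
                        categories=dict(p.categories),
                        source_person_id=p.person_id,
                    )
                )
            i += 1
        return SyntheticPopulation(area_id=area_id, persons=persons, method=method)

    def candidate(self, idx: Sequence[int]) -> Candidate:
        return Candidate(
            units=[self.units[u] for u in idx], unit_kind=self.unit_kind
        )


def _tae(counts: np.ndarray, target: np.ndarray) -> int:
    return int(np.abs(counts - target).sum())


# ---------------------------------------------------------------------------
# Simulated annealing
# ---------------------------------------------------------------------------


def simulated_annealing(
    sample: MicrodataSample,
    constraints: AreaConstraints,
    cfg: SAConfig | None = None,
    rng: np.random.Generator | int | None = None,
    schema: CategorySchema | None = None,
    unit_kind: str = "household",
) -> tuple[SyntheticPopulation, pd.DataFrame]:
    """Anneal a random candidate toward the area constraints.

    Returns the best-ever candidate (as a population) and a per-iteration
    trace with columns iteration, temperature, swap_size, current_fitness,
    best_fitness; the best-fitness column is non-increasing.
    """
    cfg = cfg or SAConfig()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if schema is None:
        from .fixtures import default_schema

        schema = default_schema()
    space = _UnitSpace(sample, schema, unit_kind)
    target = constraints.concatenated(schema)
    target_n = constraints.target_n

    idx = space.initial_candidate(target_n, rng)
    counts = space.counts(idx)
    cur_fit = _tae(counts, target)
    best_idx, best_fit = list(idx), cur_fit

    t0 = (
        cfg.initial_temperature
        if cfg.initial_temperature is not None
        else 0.1 * len(idx)
    )
    if t0 <= 0:
        raise DataError("initial temperature must be positive")

    rows = []
    for i in range(1, cfg.max_iter + 1):
        if best_fit <= cfg.fitness_threshold:
            break
        temp = cfg.temperature(i - 1, t0)  # temperature used this iteration
        n_swap = max(1, math.ceil(temp / t0 * len(idx)))
        n_swap = min(n_swap, len(idx))

        positions = rng.choice(len(idx), size=n_swap, replace=False)
        new_units = space.random_units(n_swap, rng)
        proposal = list(idx)
        removed: list[int] = []
        added: list[int] = []
        for pos, u in zip(positions, new_units):
            removed.append(proposal[pos])
            proposal[pos] = int(u)
            added.append(int(u))
        proposal, rep_added, rep_removed = space.repair_tracked(
            proposal, target_n, rng
        )
        added += rep_added
        removed += rep_removed
        new_counts = (
            counts
            + space.matrix[added].sum(axis=0, dtype=np.int64)
            - space.matrix[removed].sum(axis=0, dtype=np.int64)
        )
        new_fit = _tae(new_counts, target)

        delta_e = new_fit - cur_fit
        # once the geometric schedule underflows to 0 the walk is greedy
        accept = delta_e <= 0 or (
            temp > 0
            and rng.random() < acceptance_probability(delta_e, temp, cfg.k)
        )
        if accept:
            idx, counts, cur_fit = proposal, new_counts, new_fit
            if cur_fit < best_fit:
                best_idx, best_fit = list(idx), cur_fit
        rows.append((i, temp, n_swap, cur_fit, best_fit))

    trace = pd.DataFrame(
        rows,
        columns=[
            "iteration", "temperature", "swap_size",
            "current_fitness", "best_fitness",
        ],
    )
    return space.to_population(best_idx, constraints.area_id, "sa"), trace


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def tournament_select(
    candidates: Sequence,
    fitnesses: Sequence[float],
    size: int,
    rng: np.random.Generator,
):
    """Best (minimum-fitness) member of a uniform random entry list.

    Entrants are drawn uniformly with replacement; ties go to the earliest
    drawn entrant.
    """
    if size < 1:
        raise DataError("tournament size must be >= 1")
    if size > len(candidates):
        raise DataError("tournament size exceeds number of candidates")
    return candidates[_tournament_index(fitnesses, size, rng)]


def _tournament_index(
    fitnesses: Sequence[float], size: int, rng: np.random.Generator
) -> int:
    entrants = rng.integers(0, len(fitnesses), size=size)
    return int(min(entrants, key=lambda j: fitnesses[j]))


def _exchange_units(
    a: list, b: list, m: int, rng: np.random.Generator
) -> tuple[list, list]:
    ca, cb = list(a), list(b)
    if m > 0:
        pa = rng.choice(len(ca), size=m, replace=False)
        pb = rng.choice(len(cb), size=m, replace=False)
        for i, j in zip(pa, pb):
            ca[i], cb[j] = cb[j], ca[i]
    return ca, cb


def crossover(
    parent_a: Candidate,
    parent_b: Candidate,
    rate: float,
    rng: np.random.Generator,
) -> tuple[Candidate, Candidate]:
    """Exchange ``rate``·|units| randomly chosen units between two parents.

    The combined multiset of the two children's units equals that of the
    parents.  The exchange count rounds half-up on the smaller parent.
    """
    if parent_a.unit_kind != parent_b.unit_kind:
        raise DataError("parents must share unit_kind")
    m = _round_half_up(rate * min(len(parent_a.units), len(parent_b.units)))
    ca, cb = _exchange_units(parent_a.units, parent_b.units, m, rng)
    kind = parent_a.unit_kind
    return Candidate(ca, kind), Candidate(cb, kind)


def mutate(
    child: Candidate,
    sample: MicrodataSample,
    rate: float,
    rng: np.random.Generator,
) -> Candidate:
    """Replace ``rate``·|units| randomly chosen units with fresh draws."""
    pool = sample.households if child.unit_kind == "household" else sample.persons
    units = list(child.units)
    m = _round_half_up(rate * len(units))
    if m > 0:
        positions = rng.choice(len(units), size=m, replace=False)
        draws = rng.integers(0, len(pool), size=m)
        for pos, u in zip(positions, draws):
            units[pos] = pool[u]
    return Candidate(units, child.unit_kind)


def genetic_algorithm(
    sample: MicrodataSample,
    constraints: AreaConstraints,
    cfg: GAConfig | None = None,
    rng: np.random.Generator | int | None = None,
    schema: CategorySchema | None = None,
    unit_kind: str = "household",
) -> tuple[SyntheticPopulation, pd.DataFrame]:
    """Evolve candidate populations toward the area constraints.

    Each generation: with-replacement tournaments pick parent pairs, pairs
    are crossed over, children mutated (and, in household mode, repaired to
    the person-total band), and the children replace the parents.  The
    best candidate ever evaluated is returned together with a
    per-generation trace (generation, best_fitness, gen_best, gen_mean).
    """
    cfg = cfg or GAConfig()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if schema is None:
        from .fixtures import default_schema

        schema = default_schema()
    space = _UnitSpace(sample, schema, unit_kind)
    target = constraints.concatenated(schema)
    target_n = constraints.target_n

    population = [
        space.initial_candidate(target_n, rng)
        for _ in range(cfg.population_count)
    ]
    sizes = space._sizes_list
    totals = [sum(sizes[u] for u in c) for c in population]
    fits = list(np.abs(space.counts_batch(population) - target).sum(axis=1))
    best_j = int(np.argmin(fits))
    best_idx, best_fit = list(population[best_j]), fits[best_j]

    rows = [(0, best_fit, best_fit, float(np.mean(fits)))]
    for g in range(1, cfg.generations + 1):
        if best_fit <= 0:
            break
        children: list[list[int]] = []
        child_totals: list[int] = []
        while len(children) < cfg.population_count:
            ja = _tournament_index(fits, cfg.tournament_size, rng)
            jb = _tournament_index(fits, cfg.tournament_size, rng)
            pa, pb = population[ja], population[jb]
            ca, cb = list(pa), list(pb)
            ta, tb = totals[ja], totals[jb]
            m = _round_half_up(cfg.crossover_rate * min(len(pa), len(pb)))
            if m > 0:
                pos_a = rng.choice(len(ca), size=m, replace=False)
                pos_b = rng.choice(len(cb), size=m, replace=False)
                for i, j in zip(pos_a, pos_b):
                    ua, ub = ca[i], cb[j]
                    ca[i], cb[j] = ub, ua
                    d = sizes[ub] - sizes[ua]
                    ta += d
                    tb -= d
            for child, tot in ((ca, ta), (cb, tb)):
                if len(children) >= cfg.population_count:
                    break
                n_mut = _round_half_up(cfg.mutation_rate * len(child))
                if n_mut > 0:
                    positions = rng.choice(len(child), size=n_mut, replace=False)
                    draws = space.random_units(n_mut, rng)
                    for pos, u in zip(positions, draws):
                        u = int(u)
                        tot += sizes[u] - sizes[child[pos]]
                        child[pos] = u
                child, added, removed = space.repair_tracked(
                    child, target_n, rng, total=tot
                )
                tot += sum(sizes[u] for u in added) - sum(
                    sizes[u] for u in removed
                )
                children.append(child)
                child_totals.append(tot)
        if cfg.elitism:
            # best-ever candidate survives into the next generation
            children[0] = list(best_idx)
            child_totals[0] = sum(sizes[u] for u in best_idx)
        population = children
        totals = child_totals
        fits = list(np.abs(space.counts_batch(population) - target).sum(axis=1))
        gen_j = int(np.argmin(fits))
        if fits[gen_j] < best_fit:
            best_idx, best_fit = list(population[gen_j]), fits[gen_j]
        rows.append((g, best_fit, fits[gen_j], float(np.mean(fits))))

    trace = pd.DataFrame(
        rows, columns=["generation", "best_fitness", "gen_best", "gen_mean"]
    )
    return space.to_population(best_idx, constraints.area_id, "ga"), trace


# ---------------------------------------------------------------------------
# Random baseline
# ---------------------------------------------------------------------------


def random_baseline(
    sample: MicrodataSample,
    constraints: AreaConstraints,
    rng: np.random.Generator | int | None = None,
    schema: CategorySchema | None = None,
    unit_kind: str = "household",
) -> SyntheticPopulation:
    """Uniform with-replacement draw of survey units, no optimisation.

    Household mode draws as many households as the constraints imply the
    area holds (household count estimated from the household-size table:
    sum over sizes of count/size, the top category treated as size 8);
    person mode draws exactly ``target_n`` persons.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if schema is None:
        from .fixtures import default_schema

        schema = default_schema()
    space = _UnitSpace(sample, schema, unit_kind)
    if unit_kind == "person":
        idx = list(space.random_units(constraints.target_n, rng))
    else:
        house = constraints.counts_vector(schema, schema.resident_table)
        sizes = np.arange(1, len(house) + 1)  # top category treated as its floor
        n_households = max(1, int(round(float((house / sizes).sum()))))
        idx = list(space.random_units(n_households, rng))
    return space.to_population(idx, constraints.area_id, "random")
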