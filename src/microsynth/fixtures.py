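"""Synthetic survey microdata and ground-truth small areas.

Individual-level survey data with full category detail is access-restricted
in most countries, so this module provides a generative stand-in: a
household survey sampler with a realistic *dependency structure* between
characteristics, and an area sampler that draws true small-area populations
from locally shifted versions of the same model together with their exactly
tabulated constraint tables.

The generative model is sequential-conditional, at two levels:

* household level — a household size in 1..8 (the top category is "8 or
  more people");
* person level — age band and sex first, then marital status conditional on
  age, economic status conditional on age, and education conditional on age
  and economic status.  Children (< 15) are forced to single / not
  applicable, and students' education is "not applicable", mirroring the
  applicability rules of census questionnaires.

The point of the dependencies is not demographic realism but that the joint
distribution is far from independent, so that methods which exploit the
survey's joint structure (synthetic reconstruction, IPF seeded from the
survey cross-tabulation, combinatorial selection of real records) have
structure to recover and can be ranked against a random baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .schema import (
    AreaConstraints,
    CategorySchema,
    DataError,
    SchemaError,
)

__all__ = [
    "ConfigError",
    "PersonRecord",
    "HouseholdRecord",
    "MicrodataSample",
    "SyntheticPopulation",
    "GroundTruthArea",
    "ContingencyTensor",
    "DependencyParams",
    "ShiftParams",
    "default_schema",
    "default_params",
    "shifted_params",
    "generate_sample",
    "generate_area",
    "cross_tabulate",
    "tally",
    "constraints_from_persons",
]


class ConfigError(ValueError):
    """A generator parameter is not a valid probability specification."""


# ---------------------------------------------------------------------------
# Records and containers
# ---------------------------------------------------------------------------


@dataclass
class PersonRecord:
    """One fully categorised person: exactly one category per schema table."""

    person_id: str
    household_id: str
    categories: dict[str, str]
    source_person_id: str | None = None


@dataclass
class HouseholdRecord:
    household_id: str
    members: list[PersonRecord]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class MicrodataSample:
    """A survey: persons grouped into households."""

    households: list[HouseholdRecord]
    persons: list[PersonRecord]

    def __post_init__(self) -> None:
        if sum(h.size for h in self.households) != len(self.persons):
            raise DataError("person count does not match household sizes")
        ids = [p.person_id for p in self.persons]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate person ids")
        hids = [h.household_id for h in self.households]
        if len(set(hids)) != len(hids):
            raise DataError("duplicate household ids")


@dataclass
class SyntheticPopulation:
    """The synthesised persons of one area."""

    area_id: str
    persons: list[PersonRecord]
    method: str | None = None


@dataclass
class GroundTruthArea:
    """A true area population plus its exactly tabulated constraints."""

    area_id: str
    population: list[PersonRecord]
    constraints: AreaConstraints


@dataclass
class ContingencyTensor:
    """A dense cross-tabulation over all schema tables.

    ``values[i1, ..., ik]`` counts (or weights) persons in category ``i1``
    of the first table, ``i2`` of the second, and so on, in schema order.
    """

    dims: tuple[str, ...]
    coords: dict[str, tuple[str, ...]]
    values: np.ndarray

    def __post_init__(self) -> None:
        expected = tuple(len(self.coords[d]) for d in self.dims)
        if self.values.shape != expected:
            raise DataError(
                f"tensor shape {self.values.shape} does not match coords "
                f"{expected}"
            )
        if np.any(self.values < 0):
            raise DataError("negative tensor cell")

    @classmethod
    def zeros(cls, schema: CategorySchema, dtype=np.int64) -> "ContingencyTensor":
        dims = schema.table_names
        coords = {t: schema.categories(t) for t in dims}
        shape = tuple(len(coords[t]) for t in dims)
        return cls(dims=dims, coords=coords, values=np.zeros(shape, dtype=dtype))

    def axis_marginal(self, table: str) -> np.ndarray:
        ax = self.dims.index(table)
        other = tuple(i for i in range(len(self.dims)) if i != ax)
        return self.values.sum(axis=other)

    @property
    def total(self):
        return self.values.sum()


# ---------------------------------------------------------------------------
# Default schema (five constraint tables, census-style codes)
# ---------------------------------------------------------------------------

AGE_BANDS: tuple[tuple[int, int | None], ...] = tuple(
    [(lo, lo + 4) for lo in range(0, 85, 5)] + [(85, None)]
)
_SEXES = ("M", "F")
_MARITAL = ("SGL", "MAR", "WID", "SEP")
_ECON = ("W", "S", "LAHF", "R", "UTWSD", "OTH", "UNE")
_EDU = ("NF", "P", "LS", "US", "PLC", "HC", "DGR", "PD", "D", "NS")


def _age_code(band: int, sex: str) -> str:
    lo, hi = AGE_BANDS[band]
    mid = f"AGE{lo}_{hi}" if hi is not None else f"AGEGE{lo}"
    return f"T1_1{mid}{sex}"


def default_schema() -> CategorySchema:
    """The five-table constraint schema used throughout.

    Age-and-sex (36 categories), marital status by sex (8), household size
    (8, top-coded at "8 or more"), principal economic status by sex plus
    not-applicable (15), and highest education by sex plus not-applicable
    (21).  Economic status and education are optional-question tables;
    household size is the resident-role table that defines each area's
    target population.
    """
    age_sex = tuple(
        _age_code(b, s) for b in range(len(AGE_BANDS)) for s in _SEXES
    )
    marital = tuple(f"T1_2{m}{s}" for m in _MARITAL for s in _SEXES)
    house = tuple(
        [f"T5_2_{i}PP" for i in range(1, 8)] + ["T5_2_GE8PP"]
    )
    econ = tuple(
        [f"T8_1_{e}{s}" for e in _ECON for s in _SEXES] + ["T8_1_NA"]
    )
    edu = tuple(
        [f"T10_4_{e}{s}" for e in _EDU for s in _SEXES] + ["T10_4_NA"]
    )
    return CategorySchema(
        tables=(
            ("T1_1", age_sex),
            ("T1_2", marital),
            ("T5_2", house),
            ("T8_1", econ),
            ("T10_4", edu),
        ),
        sexed=frozenset({"T1_1", "T1_2", "T8_1", "T10_4"}),
        optional=frozenset({"T8_1", "T10_4"}),
        resident_table="T5_2",
    )


# ---------------------------------------------------------------------------
# Generative model parameters
# ---------------------------------------------------------------------------


def _norm_rows(a: np.ndarray, what: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if np.any(a < 0) or np.any(~np.isfinite(a)):
        raise ConfigError(f"{what}: probabilities must be finite and >= 0")
    s = a.sum(axis=-1, keepdims=True)
    if np.any(s <= 0):
        raise ConfigError(f"{what}: a probability row sums to zero")
    return a / s


@dataclass
class DependencyParams:
    """Probability tables of the sequential-conditional survey model.

    All rows are normalised on construction; band-indexed tables have one
    row per five-year age band (18 rows).  Children's rows of the marital /
    economic / education tables are ignored — deterministic applicability
    rules override them.
    """

    household_size_probs: np.ndarray  # sizes 1..8
    age_probs: np.ndarray  # 18 bands
    sex_probs: np.ndarray  # M, F
    marital_by_age: np.ndarray  # (18, 4): SGL MAR WID SEP
    econ_by_age: np.ndarray  # (18, 7): W S LAHF R UTWSD OTH UNE
    edu_by_age: np.ndarray  # (18, 10): NF P LS US PLC HC DGR PD D NS

    def __post_init__(self) -> None:
        self.household_size_probs = _norm_rows(
            self.household_size_probs, "household_size_probs"
        )
        if self.household_size_probs.shape != (8,):
            raise ConfigError("household_size_probs must have 8 entries")
        self.age_probs = _norm_rows(self.age_probs, "age_probs")
        if self.age_probs.shape != (len(AGE_BANDS),):
            raise ConfigError(f"age_probs must have {len(AGE_BANDS)} entries")
        self.sex_probs = _norm_rows(self.sex_probs, "sex_probs")
        if self.sex_probs.shape != (2,):
            raise ConfigError("sex_probs must have 2 entries")
        for name, arr, k in (
            ("marital_by_age", self.marital_by_age, len(_MARITAL)),
            ("econ_by_age", self.econ_by_age, len(_ECON)),
            ("edu_by_age", self.edu_by_age, len(_EDU)),
        ):
            arr = _norm_rows(arr, name)
            if arr.shape != (len(AGE_BANDS), k):
                raise ConfigError(f"{name} must be ({len(AGE_BANDS)}, {k})")
            setattr(self, name, arr)


def default_params() -> DependencyParams:
    """Moderately realistic western-European-style default parameters."""
    age = np.array(
        [5.5, 6.0, 6.5, 6.0,  # 0-19
         6.0, 6.5, 7.0, 7.5, 7.5,  # 20-44
         6.5, 6.0, 5.5, 5.0,  # 45-64
         4.5, 3.5, 2.5, 1.5, 1.0]  # 65+
    )
    marital = np.zeros((18, 4))
    marital[0:3] = [1.0, 0.0, 0.0, 0.0]  # children (overridden by rule)
    marital[3] = [0.99, 0.01, 0.0, 0.0]
    marital[4] = [0.90, 0.09, 0.0, 0.01]
    marital[5] = [0.70, 0.28, 0.0, 0.02]
    marital[6] = [0.45, 0.50, 0.005, 0.045]
    marital[7] = [0.30, 0.63, 0.01, 0.06]
    marital[8] = [0.25, 0.66, 0.01, 0.08]
    marital[9] = [0.20, 0.69, 0.02, 0.09]
    marital[10] = [0.18, 0.69, 0.03, 0.10]
    marital[11] = [0.15, 0.69, 0.06, 0.10]
    marital[12] = [0.13, 0.69, 0.09, 0.09]
    marital[13] = [0.11, 0.67, 0.14, 0.08]
    marital[14] = [0.10, 0.62, 0.21, 0.07]
    marital[15] = [0.09, 0.55, 0.31, 0.05]
    marital[16] = [0.08, 0.44, 0.44, 0.04]
    marital[17] = [0.08, 0.30, 0.59, 0.03]

    econ = np.zeros((18, 7))
    econ[0:3] = [1, 0, 0, 0, 0, 0, 0]  # children (overridden by rule)
    econ[3] = [0.12, 0.82, 0.005, 0.0, 0.005, 0.02, 0.03]
    econ[4] = [0.55, 0.30, 0.02, 0.0, 0.02, 0.03, 0.08]
    econ[5] = [0.82, 0.05, 0.04, 0.0, 0.02, 0.02, 0.05]
    econ[6:10] = [0.80, 0.01, 0.09, 0.005, 0.03, 0.015, 0.05]
    econ[10] = [0.76, 0.005, 0.10, 0.03, 0.05, 0.015, 0.04]
    econ[11] = [0.70, 0.005, 0.10, 0.10, 0.06, 0.015, 0.03]
    econ[12] = [0.52, 0.0, 0.10, 0.28, 0.06, 0.02, 0.02]
    econ[13] = [0.18, 0.0, 0.07, 0.70, 0.02, 0.02, 0.01]
    econ[14] = [0.07, 0.0, 0.05, 0.85, 0.01, 0.015, 0.005]
    econ[15:] = [0.02, 0.0, 0.03, 0.93, 0.01, 0.01, 0.0]

    edu = np.zeros((18, 10))
    edu[0:3] = [1, 0, 0, 0, 0, 0, 0, 0, 0, 0]  # children (overridden)
    edu[3] = [0.005, 0.03, 0.40, 0.45, 0.05, 0.02, 0.02, 0.0, 0.0, 0.025]
    edu[4] = [0.005, 0.01, 0.08, 0.35, 0.18, 0.09, 0.22, 0.04, 0.005, 0.02]
    edu[5:7] = [0.005, 0.01, 0.06, 0.20, 0.15, 0.10, 0.30, 0.15, 0.015, 0.01]
    edu[7:9] = [0.005, 0.015, 0.08, 0.22, 0.15, 0.10, 0.28, 0.12, 0.015, 0.015]
    edu[9:11] = [0.01, 0.03, 0.13, 0.27, 0.15, 0.09, 0.20, 0.09, 0.01, 0.02]
    edu[11:13] = [0.015, 0.06, 0.20, 0.28, 0.13, 0.08, 0.14, 0.06, 0.01, 0.025]
    edu[13:15] = [0.03, 0.12, 0.25, 0.25, 0.10, 0.06, 0.10, 0.04, 0.005, 0.045]
    edu[15:] = [0.06, 0.22, 0.27, 0.20, 0.07, 0.04, 0.07, 0.025, 0.005, 0.05]

    return DependencyParams(
        household_size_probs=np.array(
            [0.23, 0.29, 0.17, 0.17, 0.08, 0.04, 0.015, 0.005]
        ),
        age_probs=age,
        sex_probs=np.array([0.49, 0.51]),
        marital_by_age=marital,
        econ_by_age=econ,
        edu_by_age=edu,
    )


@dataclass(frozen=True)
class ShiftParams:
    """Multiplicative tilts giving an area its own demographic profile.

    ``age_tilt`` multiplies the age-band probabilities by ``tilt**band``
    (values > 1 age the area, < 1 rejuvenate it); ``size_tilt`` does the
    same for household sizes.  Tilted vectors are renormalised.
    """

    age_tilt: float = 1.0
    size_tilt: float = 1.0


def shifted_params(
    params: DependencyParams, shift: ShiftParams | None
) -> DependencyParams:
    if shift is None:
        return params
    bands = np.arange(len(AGE_BANDS))
    sizes = np.arange(8)
    return replace(
        params,
        age_probs=params.age_probs * shift.age_tilt ** bands,
        household_size_probs=(
            params.household_size_probs * shift.size_tilt ** sizes
        ),
    )


# ---------------------------------------------------------------------------
# Sampling machinery
# ---------------------------------------------------------------------------


def _sample_rows(P: np.ndarray, rows: np.ndarray, rng: np.random.Generator):
    """Draw one category per row index from row-wise distributions P."""
    cdf = np.cumsum(P, axis=1)[rows]
    u = rng.random(len(rows))
    idx = (u[:, None] > cdf).sum(axis=1)
    return np.minimum(idx, P.shape[1] - 1)


def _house_code(size: int) -> str:
    return f"T5_2_{size}PP" if size < 8 else "T5_2_GE8PP"


_ECON_IDX_S = _ECON.index("S")


def _make_persons(
    sizes: np.ndarray,
    params: DependencyParams,
    rng: np.random.Generator,
    hh_prefix: str,
    person_prefix: str,
) -> list[HouseholdRecord]:
    """Draw the members of households with the given sizes."""
    n = int(sizes.sum())
    band = _sample_rows(params.age_probs[None, :], np.zeros(n, dtype=int), rng)
    sex = _sample_rows(params.sex_probs[None, :], np.zeros(n, dtype=int), rng)
    marital = _sample_rows(params.marital_by_age, band, rng)
    econ = _sample_rows(params.econ_by_age, band, rng)
    edu = _sample_rows(params.edu_by_age, band, rng)

    child = band < 3  # under 15
    marital[child] = 0  # single
    student = econ == _ECON_IDX_S

    households: list[HouseholdRecord] = []
    j = 0
    for h, size in enumerate(sizes):
        hid = f"{hh_prefix}{h:06d}"
        house_code = _house_code(int(size))
        members = []
        for _ in range(int(size)):
            s = _SEXES[sex[j]]
            if child[j]:
                econ_code = "T8_1_NA"
                edu_code = "T10_4_NA"
            else:
                econ_code = f"T8_1_{_ECON[econ[j]]}{s}"
                edu_code = (
                    "T10_4_NA" if student[j] else f"T10_4_{_EDU[edu[j]]}{s}"
                )
            members.append(
                PersonRecord(
                    person_id=f"{person_prefix}{j:07d}",
                    household_id=hid,
                    categories={
                        "T1_1": _age_code(band[j], s),
                        "T1_2": f"T1_2{_MARITAL[marital[j]]}{s}",
                        "T5_2": house_code,
                        "T8_1": econ_code,
                        "T10_4": edu_code,
                    },
                )
            )
            j += 1
        households.append(HouseholdRecord(household_id=hid, members=members))
    return households


def generate_sample(
    schema: CategorySchema | None = None,
    n_households: int = 5000,
    params: DependencyParams | None = None,
    seed: int | np.random.Generator | None = None,
) -> MicrodataSample:
    """Draw a synthetic survey of ``n_households`` households.

    Reproducible for a fixed seed.  The default scale of 5,000 households
    (roughly 12,500 persons) is a desk-scale stand-in for a national labour
    force survey of ~31,000 individuals.
    """
    if n_households < 1:
        raise ConfigError("n_households must be >= 1")
    params = params or default_params()
    rng = np.random.default_rng(seed)
    sizes = 1 + _sample_rows(
        params.household_size_probs[None, :],
        np.zeros(n_households, dtype=int),
        rng,
    )
    households = _make_persons(sizes, params, rng, "H", "P")
    persons = [p for h in households for p in h.members]
    return MicrodataSample(households=households, persons=persons)


def generate_area(
    params: DependencyParams | None = None,
    n_persons: int = 500,
    shift: ShiftParams | None = None,
    seed: int | np.random.Generator | None = None,
    area_id: str = "A000",
) -> GroundTruthArea:
    """Draw one area's true population of exactly ``n_persons`` people.

    Households are drawn from the (optionally tilted) model until the area
    is full; the final household's size is the remaining headcount so the
    total is exact and household-size categories stay consistent.  The
    returned constraints are tabulated from the population, so they are
    exactly consistent with it.
    """
    if n_persons < 1:
        raise ConfigError("n_persons must be >= 1")
    params = shifted_params(params or default_params(), shift)
    rng = np.random.default_rng(seed)

    sizes: list[int] = []
    remaining = n_persons
    while remaining > 0:
        s = 1 + int(
            _sample_rows(
                params.household_size_probs[None, :],
                np.zeros(1, dtype=int),
                rng,
            )[0]
        )
        s = min(s, remaining)
        sizes.append(s)
        remaining -= s
    households = _make_persons(
        np.array(sizes, dtype=int), params, rng,
        f"{area_id}_H", f"{area_id}_P",
    )
    population = [p for h in households for p in h.members]
    constraints = constraints_from_persons(area_id, population)
    return GroundTruthArea(
        area_id=area_id, population=population, constraints=constraints
    )


# ---------------------------------------------------------------------------
# Tabulation
# ---------------------------------------------------------------------------


def tally(
    persons: Iterable[PersonRecord], schema: CategorySchema
) -> dict[str, np.ndarray]:
    """Per-table category counts of a person list, in schema order."""
    idx_maps = {t: schema.category_index(t) for t in schema.table_names}
    out = {
        t: np.zeros(len(schema.categories(t)), dtype=np.int64)
        for t in schema.table_names
    }
    for p in persons:
        for t, imap in idx_maps.items():
            code = p.categories.get(t)
            if code is None:
                raise DataError(
                    f"person {p.person_id} has no category for table {t}"
                )
            try:
                out[t][imap[code]] += 1
            except KeyError:
                raise SchemaError(
                    f"person {p.person_id}: code {code!r} not in table {t}"
                ) from None
    return out


def constraints_from_persons(
    area_id: str,
    persons: Sequence[PersonRecord],
    schema: CategorySchema | None = None,
) -> AreaConstraints:
    """Exact constraint tables of a known population."""
    schema = schema or default_schema()
    counts = tally(persons, schema)
    return AreaConstraints(
        area_id=area_id,
        target_n=len(persons),
        tables={
            t: dict(zip(schema.categories(t), map(int, counts[t])))
            for t in schema.table_names
        },
    )


def cross_tabulate(
    persons: Sequence[PersonRecord], schema: CategorySchema
) -> ContingencyTensor:
    """Full joint cross-tabulation of persons over all schema tables."""
    tensor = ContingencyTensor.zeros(schema)
    if not persons:
        return tensor
    idx_maps = {t: schema.category_index(t) for t in schema.table_names}
    coords = []
    for t in schema.table_names:
        imap = idx_maps[t]
        col = np.empty(len(persons), dtype=np.intp)
        for i, p in enumerate(persons):
            code = p.categories.get(t)
            if code is None:
                raise DataError(
                    f"person {p.person_id} has no category for table {t}"
                )
            try:
                col[i] = imap[code]
            except KeyError:
                raise SchemaError(
                    f"person {p.person_id}: code {code!r} not in table {t}"
                ) from None
        coords.append(col)
    np.add.at(tensor.values, tuple(coords), 1)
    return tensor
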