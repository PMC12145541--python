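"""CSV/YAML interchange and the end-to-end generation pipeline.

Formats
-------
schema        YAML or JSON: tables with ordered category codes, sexed /
              optional flags and the resident-role table.
constraints   CSV, one row per area: first column ``GUID`` (the area id),
              remaining columns named by category codes.  Rows sharing a
              GUID are summed (areas published under a duplicated id).
microdata     CSV, one row per person: ``person_id``, ``household_id``,
              one column per constraint table holding the category code.
population    CSV named ``<area_id>.csv``, one row per synthetic person;
              a ``source_person_id`` column is present when units were
              taken from the microdata directly.
reports       CSV, one row per area x table plus one summary row per area.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from . import co, ipf, sr
from .fixtures import (
    HouseholdRecord,
    MicrodataSample,
    PersonRecord,
    SyntheticPopulation,
    cross_tabulate,
)
from .schema import (
    AreaConstraints,
    CategorySchema,
    DataError,
    RawAreaTable,
    SchemaError,
    harmonise_area,
)
from .validate import FitReport, evaluate_area, summarise_runs

logger = logging.getLogger("microsynth")

__all__ = [
    "load_schema",
    "save_schema",
    "read_constraints_csv",
    "load_constraints",
    "write_constraints_csv",
    "read_microdata_csv",
    "write_microdata_csv",
    "write_population",
    "read_population",
    "write_reports",
    "RunConfig",
    "area_seed",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# Schema files
# ---------------------------------------------------------------------------


def load_schema(path: str | Path) -> CategorySchema:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return CategorySchema.from_dict(data)


def save_schema(schema: CategorySchema, path: str | Path) -> Path:
    path = Path(path)
    d = schema.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    return path


# ---------------------------------------------------------------------------
# Constraints
# ---------------------------------------------------------------------------


def read_constraints_csv(
    path: str | Path, schema: CategorySchema
) -> dict[str, list[RawAreaTable]]:
    """Raw per-area tables from a wide CSV (GUID + category columns)."""
    df = pd.read_csv(path, dtype={0: str})
    id_col = df.columns[0]
    code_to_table = {
        code: name for name, cats in schema.tables for code in cats
    }
    unknown = [
        c for c in df.columns[1:] if c not in code_to_table
    ]
    if unknown:
        raise SchemaError(f"constraint columns not in schema: {unknown}")
    out: dict[str, list[RawAreaTable]] = {}
    for _, row in df.iterrows():
        area_id = str(row[id_col])
        per_table: dict[str, dict[str, int]] = {}
        for code in df.columns[1:]:
            v = row[code]
            if pd.isna(v):
                continue
            per_table.setdefault(code_to_table[code], {})[code] = int(v)
        out.setdefault(area_id, []).extend(
            RawAreaTable(area_id, t, counts) for t, counts in per_table.items()
        )
    return out


def load_constraints(
    path: str | Path, schema: CategorySchema, **harmonise_kwargs
) -> list[AreaConstraints]:
    """Read, merge duplicate areas and harmonise every area."""
    raw = read_constraints_csv(path, schema)
    return [
        harmonise_area(tables, schema, **harmonise_kwargs)
        for _, tables in sorted(raw.items())
    ]


def write_constraints_csv(
    areas: Iterable[AreaConstraints], path: str | Path, schema: CategorySchema
) -> Path:
    path = Path(path)
    codes = [c for _, cats in schema.tables for c in cats]
    rows = []
    for a in areas:
        row: dict = {"GUID": a.area_id}
        for t, counts in a.tables.items():
            row.update(counts)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["GUID"] + codes)
    df[codes] = df[codes].fillna(0).astype(np.int64)
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Microdata
# ---------------------------------------------------------------------------


def write_microdata_csv(
    sample: MicrodataSample, path: str | Path, schema: CategorySchema
) -> Path:
    path = Path(path)
    cols = ["person_id", "household_id"] + list(schema.table_names)
    rows = [
        [p.person_id, p.household_id]
        + [p.categories[t] for t in schema.table_names]
        for p in sample.persons
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    return path


def read_microdata_csv(
    path: str | Path, schema: CategorySchema
) -> MicrodataSample:
    df = pd.read_csv(path, dtype=str)
    needed = {"person_id", "household_id", *schema.table_names}
    missing = needed - set(df.columns)
    if missing:
        raise SchemaError(f"microdata missing columns: {sorted(missing)}")
    households: dict[str, HouseholdRecord] = {}
    persons: list[PersonRecord] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        p = PersonRecord(
            person_id=d["person_id"],
            household_id=d["household_id"],
            categories={t: d[t] for t in schema.table_names},
        )
        persons.append(p)
        hh = households.setdefault(
            p.household_id, HouseholdRecord(p.household_id, [])
        )
        hh.members.append(p)
    return MicrodataSample(households=list(households.values()), persons=persons)


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------


def write_population(
    pop: SyntheticPopulation, directory: str | Path, schema: CategorySchema
) -> Path:
    """One CSV per area, named after the area id, one row per person."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{pop.area_id}.csv"
    with_source = any(p.source_person_id for p in pop.persons)
    cols = ["person_id", "household_id"]
    if with_source:
        cols.append("source_person_id")
    cols += list(schema.table_names)
    rows = []
    for p in pop.persons:
        row = [p.person_id, p.household_id]
        if with_source:
            row.append(p.source_person_id or "")
        row += [p.categories[t] for t in schema.table_names]
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    return path


def read_population(
    path: str | Path, schema: CategorySchema, method: str | None = None
) -> SyntheticPopulation:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    persons = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        persons.append(
            PersonRecord(
                person_id=d["person_id"],
                household_id=d.get("household_id", d["person_id"]),
                categories={t: d[t] for t in schema.table_names},
                source_person_id=d.get("source_person_id") or None,
            )
        )
    return SyntheticPopulation(
        area_id=path.stem, persons=persons, method=method
    )


def write_reports(
    reports: Iterable[FitReport], path: str | Path
) -> Path:
    path = Path(path)
    rows = []
    for rep in reports:
        for tf in rep.tables:
            rows.append(
                {
                    "area_id": rep.area_id,
                    "method": rep.method,
                    "row_kind": "table",
                    "table": tf.table_name,
                    "r": tf.r,
                    "rmse": tf.rmse,
                    "x2": tf.x2,
                    "z2": tf.z2,
                    "df": tf.df,
                    "x2_pass": tf.x2_pass,
                    "z2_pass": tf.z2_pass,
                }
            )
        rows.append(
            {
                "area_id": rep.area_id,
                "method": rep.method,
                "row_kind": "area",
                "table": "",
                "r": rep.overall_r,
                "rmse": rep.overall_rmse,
                "x2": np.nan,
                "z2": np.nan,
                "df": np.nan,
                "x2_pass": rep.nft_x2,  # NFT counts in the summary row
                "z2_pass": rep.nft_z2,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """One end-to-end generation run over every area in a constraints file."""

    method: str  # sr | ipf | sa | ga | random
    constraints_path: str | Path
    microdata_path: str | Path
    schema_path: str | Path
    out_dir: str | Path
    seed: int = 0
    unit_kind: str = "household"
    alpha: float = 0.05
    sa: co.SAConfig | None = None
    ga: co.GAConfig | None = None
    sr_policy: sr.SRPolicy | None = None
    ipf_tol: float = 1e-8
    ipf_max_iter: int = 1000

    def __post_init__(self) -> None:
        if self.method not in ("sr", "ipf", "sa", "ga", "random"):
            raise DataError(f"unknown method {self.method!r}")


def area_seed(master_seed: int, area_id: str) -> int:
    """Deterministic, order-insensitive per-area seed (< 2**31)."""
    return (int(master_seed) ^ zlib.crc32(area_id.encode())) & 0x7FFFFFFF


def synthesize_one(
    method: str,
    constraints: AreaConstraints,
    sample: MicrodataSample,
    schema: CategorySchema,
    rng: np.random.Generator,
    *,
    unit_kind: str = "household",
    sa_cfg: co.SAConfig | None = None,
    ga_cfg: co.GAConfig | None = None,
    sr_policy: sr.SRPolicy | None = None,
    seed_tensor=None,
    ipf_tol: float = 1e-8,
    ipf_max_iter: int = 1000,
) -> SyntheticPopulation:
    """Dispatch one area to the chosen generation method."""
    if method == "sr":
        return sr.synthesize_population_sr(
            constraints, sample, sr_policy, rng, schema
        )
    if method == "ipf":
        seed_tensor = (
            seed_tensor
            if seed_tensor is not None
            else cross_tabulate(sample.persons, schema)
        )
        weights, report = ipf.ipf_fit(
            seed_tensor, constraints, tol=ipf_tol, max_iter=ipf_max_iter
        )
        if not report.converged:
            logger.warning(
                "area %s: IPF did not fully converge "
                "(max deviation %.3g, unreachable %s)",
                constraints.area_id, report.max_deviation, report.unreachable,
            )
        integer = ipf.trs_integerise(weights, constraints.target_n, rng)
        return ipf.expand_to_population(integer, schema, constraints.area_id)
    if method == "sa":
        pop, _ = co.simulated_annealing(
            sample, constraints, sa_cfg, rng, schema, unit_kind
        )
        return pop
    if method == "ga":
        pop, _ = co.genetic_algorithm(
            sample, constraints, ga_cfg, rng, schema, unit_kind
        )
        return pop
    if method == "random":
        return co.random_baseline(sample, constraints, rng, schema, unit_kind)
    raise DataError(f"unknown method {method!r}")


def run_pipeline(config: RunConfig) -> tuple[list[FitReport], dict]:
    """Harmonise, synthesise, evaluate and write every area.

    Per-area failures are logged and skipped; only setup errors raise.
    Returns the fit reports and the cross-area summary tables.
    """
    schema = load_schema(config.schema_path)
    areas = load_constraints(config.constraints_path, schema)
    sample = read_microdata_csv(config.microdata_path, schema)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pop_dir = out_dir / "populations"

    seed_tensor = (
        cross_tabulate(sample.persons, schema) if config.method == "ipf" else None
    )
    reports: list[FitReport] = []
    for constraints in areas:
        try:
            rng = np.random.default_rng(
                area_seed(config.seed, constraints.area_id)
            )
            pop = synthesize_one(
                config.method,
                constraints,
                sample,
                schema,
                rng,
                unit_kind=config.unit_kind,
                sa_cfg=config.sa,
                ga_cfg=config.ga,
                sr_policy=config.sr_policy,
                seed_tensor=seed_tensor,
                ipf_tol=config.ipf_tol,
                ipf_max_iter=config.ipf_max_iter,
            )
            write_population(pop, pop_dir, schema)
            rep = evaluate_area(pop, constraints, schema, config.alpha)
            rep.method = config.method
            reports.append(rep)
            logger.info(
                "area %s: n=%d R=%.4f RMSE=%.3f NFT(X2)=%d NFT(Z2)=%d",
                constraints.area_id, constraints.target_n,
                rep.overall_r, rep.overall_rmse, rep.nft_x2, rep.nft_z2,
            )
        except Exception:
            logger.exception("area %s failed; skipping", constraints.area_id)
    if not reports:
        raise DataError("every area failed")
    summary = summarise_runs(reports)
    write_reports(reports, out_dir / "reports.csv")
    summary["overall"].to_csv(out_dir / "summary_overall.csv")
    summary["by_table_r"].to_csv(out_dir / "summary_by_table_r.csv")
    summary["by_table_rmse"].to_csv(out_dir / "summary_by_table_rmse.csv")
    summary["nft_x2"].to_csv(out_dir / "summary_nft_x2.csv")
    summary["nft_z2"].to_csv(out_dir / "summary_nft_z2.csv")
    return reports, summary
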