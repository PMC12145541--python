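"""Goodness-of-fit validation of synthetic populations.

For each area the synthetic population's tabulated counts are compared to
the constraint tables with:

* Pearson correlation R and RMSE — overall (all tables' cells concatenated
  into one vector) and per characteristic table;
* the Pearson goodness-of-fit statistic X² = Σ (Tᵢ − Eᵢ)²/Eᵢ, with an
  expected count of 0 replaced by 1 (the statistic is undefined at 0);
* the Z² statistic: per cell, a normal approximation to the binomial
  proportion with a ±1/(2N) continuity correction — added when the expected
  proportion exceeds the observed, subtracted when it falls below — and an
  expected proportion of 0 replaced by 1/N with no correction applied;
  Z² is the sum of squared cell Z-scores;
* a χ² test of each statistic at significance level α (default 0.05) with
  degrees of freedom equal to the table's cell count; a table whose
  statistic exceeds the critical value is a non-fitting table (NFT).

Both statistics follow Voas & Williamson's small-area validation
conventions.  NFT counts per area (0 to the number of evaluated tables,
5 in the default schema) summarise fit at the area level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fixtures import PersonRecord, SyntheticPopulation, tally
from .schema import AreaConstraints, CategorySchema, DataError

__all__ = [
    "TableFit",
    "FitReport",
    "pearson_r",
    "rmse",
    "pearson_x2",
    "z_score",
    "z2_statistic",
    "chi2_decide",
    "evaluate_area",
    "summarise_runs",
]


@dataclass
class TableFit:
    """Fit diagnostics of one constraint table."""

    table_name: str
    observed: np.ndarray  # synthetic counts T_i
    expected: np.ndarray  # constraint counts E_i
    observed_prop: np.ndarray  # t_i
    expected_prop: np.ndarray  # p_i
    n: int  # total observed count N
    r: float
    rmse: float
    x2: float
    z2: float
    df: int
    x2_pass: bool
    z2_pass: bool


@dataclass
class FitReport:
    """All validation results for one synthesised area."""

    area_id: str
    tables: list[TableFit]
    overall_r: float
    overall_rmse: float
    nft_x2: int
    nft_z2: int
    method: str | None = None


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------


def pearson_r(observed: Sequence[float], expected: Sequence[float]) -> float:
    """Product-moment correlation between observed and expected cells."""
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if o.shape != e.shape or o.ndim != 1 or len(o) < 2:
        raise DataError("pearson_r needs two equal-length vectors of >= 2")
    if np.ptp(o) == 0 or np.ptp(e) == 0:
        raise DataError("correlation undefined for a constant vector")
    return float(stats.pearsonr(o, e).statistic)


def rmse(observed: Sequence[float], expected: Sequence[float]) -> float:
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if o.shape != e.shape or o.ndim != 1 or len(o) < 1:
        raise DataError("rmse needs two equal-length vectors")
    return float(np.sqrt(np.mean((o - e) ** 2)))


def pearson_x2(observed: Sequence[float], expected: Sequence[float]) -> float:
    """Pearson goodness-of-fit statistic with zero-expected substitution.

    An expected count of 0 is replaced by 1 (in both the numerator's
    deviation and the denominator), keeping the statistic defined.
    """
    t = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if t.shape != e.shape:
        raise DataError("shape mismatch")
    if np.any(t < 0) or np.any(e < 0):
        raise DataError("counts must be non-negative")
    e_sub = np.where(e == 0, 1.0, e)
    return float((((t - e_sub) ** 2) / e_sub).sum())


def z_score(t_i: float, p_i: float, n: int) -> float:
    """Continuity-corrected normal-approximation Z-score for one cell.

    ``t_i`` is the observed (synthetic) proportion, ``p_i`` the expected
    proportion and ``n`` the table's total observed count.  The ±1/(2N)
    correction is added when p > t and subtracted when p < t (at a tie the
    positive sign is applied).  A zero expected proportion is replaced by
    1/N and then no correction is applied.
    """
    if n <= 0:
        raise DataError("N must be positive")
    if not (0.0 <= t_i <= 1.0 and 0.0 <= p_i <= 1.0):
        raise DataError("proportions must lie in [0, 1]")
    if p_i == 0:
        p = 1.0 / n  # substituted everywhere; no continuity correction
        corr = 0.0
    else:
        p = p_i
        corr = 1.0 / (2 * n) if p_i >= t_i else -1.0 / (2 * n)
    if p >= 1.0:
        raise DataError("zero variance: expected proportion is 1")
    return float(((t_i - p) + corr) / np.sqrt(p * (1.0 - p) / n))


def z2_statistic(
    observed_prop: Sequence[float],
    expected_prop: Sequence[float],
    n: int,
) -> float:
    """Sum of squared per-cell Z-scores for one table."""
    t = np.asarray(observed_prop, dtype=float)
    p = np.asarray(expected_prop, dtype=float)
    if t.shape != p.shape:
        raise DataError("shape mismatch")
    return float(sum(z_score(ti, pi, n) ** 2 for ti, pi in zip(t, p)))


def chi2_decide(statistic: float, df: int, alpha: float = 0.05) -> bool:
    """True (the table fits) iff the statistic does not exceed the χ²
    critical value at confidence level 1−α with ``df`` degrees of freedom."""
    if df < 1:
        raise DataError("df must be >= 1")
    critical = stats.chi2.ppf(1.0 - alpha, df)
    return bool(statistic <= critical)


# ---------------------------------------------------------------------------
# Area-level evaluation
# ---------------------------------------------------------------------------


def _safe_r(o: np.ndarray, e: np.ndarray) -> float:
    try:
        return pearson_r(o, e)
    except DataError:
        return float("nan")


def evaluate_area(
    population: SyntheticPopulation | Sequence[PersonRecord],
    constraints: AreaConstraints,
    schema: CategorySchema,
    alpha: float = 0.05,
) -> FitReport:
    """Full fit report of one synthetic population against its constraints."""
    if isinstance(population, SyntheticPopulation):
        persons = population.persons
        method = population.method
        area_id = population.area_id
    else:
        persons = list(population)
        method = None
        area_id = constraints.area_id
    if not persons:
        raise DataError("cannot evaluate an empty population")

    counts = tally(persons, schema)
    tables: list[TableFit] = []
    all_obs: list[np.ndarray] = []
    all_exp: list[np.ndarray] = []
    for t in schema.table_names:
        obs = counts[t].astype(float)
        exp = constraints.counts_vector(schema, t).astype(float)
        n = int(obs.sum())
        obs_p = obs / n if n > 0 else obs
        exp_total = exp.sum()
        exp_p = exp / exp_total if exp_total > 0 else exp
        x2 = pearson_x2(obs, exp)
        z2 = z2_statistic(obs_p, exp_p, n)
        df = len(obs)
        tables.append(
            TableFit(
                table_name=t,
                observed=obs.astype(np.int64),
                expected=exp.astype(np.int64),
                observed_prop=obs_p,
                expected_prop=exp_p,
                n=n,
                r=_safe_r(obs, exp),
                rmse=rmse(obs, exp),
                x2=x2,
                z2=z2,
                df=df,
                x2_pass=chi2_decide(x2, df, alpha),
                z2_pass=chi2_decide(z2, df, alpha),
            )
        )
        all_obs.append(obs)
        all_exp.append(exp)

    obs_cat = np.concatenate(all_obs)
    exp_cat = np.concatenate(all_exp)
    return FitReport(
        area_id=area_id,
        tables=tables,
        overall_r=_safe_r(obs_cat, exp_cat),
        overall_rmse=rmse(obs_cat, exp_cat),
        nft_x2=sum(not tf.x2_pass for tf in tables),
        nft_z2=sum(not tf.z2_pass for tf in tables),
        method=method,
    )


def summarise_runs(reports: Iterable[FitReport]) -> dict[str, pd.DataFrame]:
    """Cross-area summaries, grouped by method.

    Returns a dict of DataFrames: ``overall`` (median overall R and RMSE
    per method), ``by_table_r`` / ``by_table_rmse`` (per-characteristic
    medians) and ``nft_x2`` / ``nft_z2`` (histograms of NFT counts).
    """
    reports = list(reports)
    if not reports:
        raise DataError("no reports to summarise")
    rows = []
    table_rows = []
    for rep in reports:
        method = rep.method or "unknown"
        rows.append(
            {
                "method": method,
                "area_id": rep.area_id,
                "overall_r": rep.overall_r,
                "overall_rmse": rep.overall_rmse,
                "nft_x2": rep.nft_x2,
                "nft_z2": rep.nft_z2,
            }
        )
        for tf in rep.tables:
            table_rows.append(
                {
                    "method": method,
                    "area_id": rep.area_id,
                    "table": tf.table_name,
                    "r": tf.r,
                    "rmse": tf.rmse,
                }
            )
    df = pd.DataFrame(rows)
    tdf = pd.DataFrame(table_rows)
    n_tables = max(len(rep.tables) for rep in reports)
    bins = list(range(n_tables + 1))

    def nft_hist(col: str) -> pd.DataFrame:
        return (
            df.groupby("method")[col]
            .value_counts()
            .unstack(fill_value=0)
            .reindex(columns=bins, fill_value=0)
        )

    return {
        "overall": df.groupby("method")[["overall_r", "overall_rmse"]].median(),
        "by_table_r": tdf.pivot_table(
            index="method", columns="table", values="r", aggfunc="median"
        ),
        "by_table_rmse": tdf.pivot_table(
            index="method", columns="table", values="rmse", aggfunc="median"
        ),
        "nft_x2": nft_hist("nft_x2"),
        "nft_z2": nft_hist("nft_z2"),
    }
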