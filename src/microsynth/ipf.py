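"""Iterative proportional fitting, TRS integerisation, person expansion.

IPF (raking) rescales a seed cross-tabulation — here the survey's joint
distribution of all constraint characteristics — so that every axis
marginal matches an area's constraint totals, while preserving the seed's
interaction structure (all cross-product ratios among positive cells).
Structural zeros of the seed remain zero.

The fractional weight tensor is turned into whole persons by
truncate-replicate-sample (TRS): floor every weight, then allocate the
remaining units without replacement with probability proportional to the
fractional parts.  Expansion then emits one person per unit count carrying
that cell's category combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fixtures import ContingencyTensor, PersonRecord, SyntheticPopulation
from .schema import AreaConstraints, CategorySchema, DataError

__all__ = ["IPFReport", "ipf_fit", "trs_integerise", "expand_to_population"]


@dataclass
class IPFReport:
    """Convergence diagnostics of one IPF run."""

    converged: bool
    n_iter: int
    max_deviation: float
    unreachable: list[tuple[str, str]] = field(default_factory=list)

    def __bool__(self) -> bool:  # truthy iff converged
        return self.converged


def ipf_fit(
    seed: ContingencyTensor,
    marginals: AreaConstraints,
    tol: float = 1e-8,
    max_iter: int = 1000,
    smoothing: float = 0.0,
) -> tuple[ContingencyTensor, IPFReport]:
    """Rake a seed tensor to the area's marginal constraint totals.

    One sweep scales each axis once, in schema (tensor-dim) order:
    every slice of the axis is multiplied by target-sum / current-sum.
    Convergence is reached when the largest absolute deviation of any axis
    marginal from its target is at most ``tol`` (in persons).

    Empty seed cells stay zero by default, preserving the survey's
    structural zeros; ``smoothing`` adds a constant to every cell first,
    trading structural fidelity for reachability of rare categories.

    A marginal category with a positive target whose seed slice is entirely
    zero is unreachable: it is reported in ``IPFReport.unreachable`` and the
    run is flagged non-converged (the slice stays zero, as scaling cannot
    create mass).
    """
    if tol <= 0:
        raise DataError("tol must be positive")
    if smoothing < 0:
        raise DataError("smoothing must be >= 0")
    if smoothing > 0:
        seed = ContingencyTensor(
            dims=seed.dims,
            coords=dict(seed.coords),
            values=seed.values + smoothing,
        )
    w = seed.values.astype(float).copy()
    dims = seed.dims
    ndim = len(dims)
    targets = []
    for ax, table in enumerate(dims):
        t = np.array(
            [marginals.tables[table].get(c, 0) for c in seed.coords[table]],
            dtype=float,
        )
        targets.append(t)
    totals = {round(float(t.sum())) for t in targets}
    if len(totals) > 1:
        raise DataError(
            f"marginal tables disagree on the total population: {sorted(totals)}"
        )

    # unreachable slices: positive target over an all-zero seed slice
    unreachable: list[tuple[str, str]] = []
    for ax, table in enumerate(dims):
        other = tuple(i for i in range(ndim) if i != ax)
        slice_mass = seed.values.sum(axis=other)
        for i, cat in enumerate(seed.coords[table]):
            if targets[ax][i] > 0 and slice_mass[i] == 0:
                unreachable.append((table, cat))

    def max_dev(arr: np.ndarray) -> float:
        d = 0.0
        for ax in range(ndim):
            other = tuple(i for i in range(ndim) if i != ax)
            cur = arr.sum(axis=other)
            d = max(d, float(np.abs(cur - targets[ax]).max()))
        return d

    n_iter = 0
    dev = max_dev(w)
    while dev > tol and n_iter < max_iter:
        for ax in range(ndim):
            other = tuple(i for i in range(ndim) if i != ax)
            cur = w.sum(axis=other)
            with np.errstate(divide="ignore", invalid="ignore"):
                factor = np.where(cur > 0, targets[ax] / np.where(cur > 0, cur, 1.0), 1.0)
            shape = [1] * ndim
            shape[ax] = len(factor)
            w *= factor.reshape(shape)
        n_iter += 1
        dev = max_dev(w)

    report = IPFReport(
        converged=(dev <= tol and not unreachable),
        n_iter=n_iter,
        max_deviation=dev,
        unreachable=unreachable,
    )
    return (
        ContingencyTensor(dims=dims, coords=dict(seed.coords), values=w),
        report,
    )


def trs_integerise(
    weights: ContingencyTensor | np.ndarray,
    target_n: int,
    rng: np.random.Generator | int | None = None,
) -> ContingencyTensor | np.ndarray:
    """Truncate-replicate-sample integerisation of fractional weights.

    Floors every weight (truncate -> replicate whole persons), then draws
    the remaining ``target_n - sum(floors)`` units without replacement
    among cells with probability proportional to the fractional parts.
    The result always sums exactly to ``target_n`` and never falls below
    the floor of any cell.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    is_tensor = isinstance(weights, ContingencyTensor)
    arr = weights.values if is_tensor else np.asarray(weights, dtype=float)
    if np.any(arr < 0):
        raise DataError("negative weight")
    flat = arr.reshape(-1)
    base = np.floor(flat).astype(np.int64)
    n_extra = int(target_n) - int(base.sum())
    if n_extra < 0:
        raise DataError(
            f"sum of floored weights {int(base.sum())} exceeds target {target_n}"
        )
    out = base.copy()
    if n_extra > 0:
        frac = flat - base
        positive = np.flatnonzero(frac > 0)
        if len(positive) < n_extra:
            raise DataError(
                "not enough fractional mass to reach the target total"
            )
        p = frac[positive] / frac[positive].sum()
        chosen = rng.choice(positive, size=n_extra, replace=False, p=p)
        out[chosen] += 1
    result = out.reshape(arr.shape)
    if is_tensor:
        return ContingencyTensor(
            dims=weights.dims, coords=dict(weights.coords), values=result
        )
    return result


def expand_to_population(
    tensor: ContingencyTensor,
    schema: CategorySchema,
    area_id: str,
    method: str = "ipf",
) -> SyntheticPopulation:
    """One person per unit count, carrying the cell's category combination."""
    values = tensor.values
    if not np.issubdtype(values.dtype, np.integer):
        if not np.all(values == np.round(values)):
            raise DataError("expand_to_population requires integer counts")
        values = values.astype(np.int64)
    persons: list[PersonRecord] = []
    i = 0
    for idx in zip(*np.nonzero(values)):
        cats = {
            table: tensor.coords[table][idx[ax]]
            for ax, table in enumerate(tensor.dims)
        }
        for _ in range(int(values[idx])):
            persons.append(
                PersonRecord(
                    person_id=f"{area_id}_{method}_{i:06d}",
                    household_id=f"{area_id}_{method}_{i:06d}",
                    categories=dict(cats),
                )
            )
            i += 1
    return SyntheticPopulation(area_id=area_id, persons=persons, method=method)
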