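# Methods

This note describes the models and procedures implemented in `microsynth`,
the choices made where the design was genuinely open, and what the
synthetic test bed can and cannot show about real census/survey data.

## Problem setting

Spatial microsimulation needs an individual-level population for every
small area, but published data come in two disjoint halves: *aggregate
constraint tables* (per-area counts of people per category of each
characteristic, as in census small-area statistics) and *survey microdata*
(fully categorised individuals with household identifiers, but no
small-area geography).  The package synthesises a population per area that
is consistent with the area's constraint tables while inheriting the
survey's joint distribution of characteristics.

Five characteristics constrain each person: age band and sex (36
categories), marital status by sex (8), household size (8, top-coded at
"8 or more people"), principal economic status by sex plus a
not-applicable category (15), and highest education by sex plus
not-applicable (21) — 88 cells across 5 tables.

## Aggregate harmonisation

Raw constraint tables of one area rarely share a total: questions are
optional or restricted (education is not asked of children or students),
and different tables cover different population universes (communal
housing, absent residents).  Harmonisation proceeds per area:

1. duplicate published rows for one area identifier are summed;
2. detailed source categories are merged to the survey coding
   (configurable merge maps; e.g. separated + divorced, the three
   unemployment types, ISCED-to-local education recoding), and
   single-year age counts are combined into five-year bands;
3. the total of the household-size table (universe: persons usually
   resident in private households) defines the area target `target_n`;
4. optional-question tables falling short of `target_n` are padded with an
   explicit `<table>_NA` category; every other mismatch (up or down) is
   integer-rescaled to `target_n`.

Rescaling uses a deterministic largest-remainder sweep (the integer
error-accumulator of Bresenham's line algorithm): each cell gets the floor
of its exact proportional share and leftover units go to the largest
fractional remainders, ties to the earliest schema position.  All
arithmetic is exact integer arithmetic, so `sum(out) == target` always and
every cell is strictly within one person of its exact share.  Whether an
undercounting *mandatory* table is rescaled up (default) or NA-padded is a
flag; published sources do not state a rule.

## Generation methods

All methods consume harmonised constraints and the survey, and emit
exactly comparable person lists.

**Synthetic reconstruction (SR)** builds persons one characteristic at a
time.  The first characteristic is drawn from the area marginal; later
ones from survey conditionals given everything assigned so far.  Open
choices and their defaults:

* *First-table draws*: without-replacement depletion of the remaining area
  marginal (default; guarantees the first table fits exactly) or plain
  with-replacement Monte-Carlo draws from the target proportions.
* *Sampling order*: fixed (default, schema order) or adaptive — before
  each person, the table whose running synthetic proportions deviate most
  (max absolute difference) from the target proportions is sampled first,
  ties broken by base-order position.
* *Empty cells*: when no survey record matches the current conditions the
  most recently added condition is dropped and the lookup retried,
  recursing to the unconditional marginal.  This is deterministic and
  always terminates; it biases the affected person toward the survey's
  less-conditioned distribution, which is the price of a finite survey.

Bulk synthesis serves conditionals from the survey's precomputed joint
cross-tabulation (identical numbers to filter-and-count, verified in
tests).

**Iterative proportional fitting (IPF)** rakes the survey's full joint
cross-tabulation (the seed) so every axis marginal matches the area's
tables.  One sweep scales each axis once in schema order; convergence is
max absolute marginal deviation ≤ `tol` (default 1e-8 persons, max 1000
sweeps).  Structural zeros of the seed stay zero (no smoothing by
default; additive smoothing is available as a flag).  A positive marginal
target over an all-zero seed slice is unreachable: it is reported by name
and the run flagged non-converged.  Fractional weights are integerised by
truncate-replicate-sample (TRS): floor everything, then allocate the
remaining units without replacement with probability proportional to the
fractional parts — totals are exact by construction.  Quasirandom integer
sampling is deliberately not implemented.

**Simulated annealing (SA)** and the **genetic algorithm (GA)** select
actual survey units — households by default, persons optionally — to
minimise total absolute error (TAE): the sum over all 88 constraint cells
of |tabulated − target|.  TAE is zero exactly at a perfect fit,
integer-valued, monotone in per-cell deviations, and cheap to evaluate
incrementally; it is the conventional objective for combinatorial
spatial microsimulation.

SA details: initial temperature defaults to 0.1 × the initial household
count; each iteration proposes swapping `max(1, ceil(T/T0 × units))`
randomly chosen units for fresh uniform draws, accepts improvements
always and worsenings with probability `exp(−ΔE/kT)` (k = 1), then cools
by the factor 0.85.  The run stops when fitness reaches the threshold
(default 0) or at `max_iter` (default 100 000 — the cap is a safety
valve; the fitness threshold is the intended stop rule.  Time-to-exact-fit
is heavy-tailed even on 100-person areas: typically a few thousand
single-swap iterations, occasionally tens of thousands, so the cap sits an
order of magnitude above the typical scale.  Iterations are
delta-evaluated, so a capped run costs a few seconds).  After ~4 700 cooling steps the schedule
underflows to zero and the walk is purely greedy (equal-fitness moves are
still accepted, which lets it traverse plateaus).  In household mode a
candidate may overshoot the target headcount by part of one household;
a repair step keeps the overshoot below the largest household size.

GA details (rates follow the conventional published parameterisation):
100 candidate populations, tournaments of size 10 drawn with replacement,
crossover exchanging 0.7 × |units| randomly chosen units between the two
parents (the children's combined unit multiset equals the parents'),
mutation replacing 0.05 × |units| units with fresh draws, children
replacing parents wholesale, no elitism, 100 generations by default, and
the best candidate ever evaluated is returned.

**Random baseline**: draw uniformly, with replacement, as many households
as the household-size table implies the area holds (Σ count/size, the top
category treated as size 8); no optimisation.

### Exact-recovery behaviour of the optimisers

When the survey contains the area's own households an exact (TAE 0)
solution exists.  Whether the optimisers reach it depends strongly on
candidate size:

* SA's end-game is single blind swaps; the probability that one swap both
  removes a surplus unit and inserts a deficit unit falls roughly with the
  square of the candidate size.  Exact recovery is reliable up to roughly
  100-person areas and stalls in the tens of TAE for areas of several
  hundred, even with very large iteration budgets.
* The generational, no-elitism GA carries a mutation/recombination load
  proportional to candidate size, so its population equilibrates at a
  positive TAE for anything beyond a few dozen persons; exact recovery is
  only expected on areas of that scale.

The recovery tests therefore exercise SA on 100-person areas and the GA
on 30-person areas.  Neither limitation affects the methods' *statistical*
fit on realistic areas, which is what the benchmark measures — both sit at
the top of the ranking there.

## Validation

Per area and per table: Pearson R and RMSE on the cell counts, the
Pearson statistic X² = Σ(Tᵢ−Eᵢ)²/Eᵢ, and Z² = Σzᵢ² from the
continuity-corrected normal approximation to each cell's binomial
proportion, z = ((t−p) ± 1/(2N)) / √(p(1−p)/N), with the correction added
when p > t and subtracted when p < t.  Overall R and RMSE concatenate all
88 cells.  Conventions adopted where sources are silent:

* X² zero-expected substitution (E=0 → 1) applies in both numerator and
  denominator; consequently a cell empty on both sides contributes 1, so
  X² is zero only for a perfect fit with all cells positive.
* At a tie t = p the continuity correction is applied with positive sign
  (both signs inflate |z| equally; a fixed choice keeps results
  deterministic).
* A zero expected proportion is replaced by 1/N everywhere in the formula
  and the correction is dropped.

Each statistic is tested against the χ² critical value with degrees of
freedom equal to the table's cell count at α = 0.05 (strict exceedance
fails); a failing table is a non-fitting table (NFT), and an area's NFT
count ranges 0–5.  Note that Z² ≈ X² only when all cell proportions are
small (the two differ cellwise by 1/(1−pᵢ)); for the many-category tables
used here the difference is a few percent.

## Synthetic test bed

Because real survey microdata of this kind is access-restricted, all
tests run against a generative stand-in with known ground truth.  The
survey model is sequential-conditional: household size (1–8), then per
person age band and sex, marital status | age, economic status | age, and
education | age and economic status, with hard applicability rules
(children single/not-applicable; students' education not applicable).
Parameter tables are moderately realistic western-European-style values
chosen once; the default survey is 5 000 households (~12 500 persons), a
desk-scale stand-in for a ~31 000-person national labour force survey.
Areas are drawn from the same model with per-area multiplicative tilts on
the age and household-size distributions (log-normal tilts, σ = 0.05 and
0.08), giving spatial heterogeneity, and their constraints are tabulated
exactly from the drawn population.

The benchmark (`microsynth.benchmark.run_benchmark`, also what
`scripts/acceptance.py` runs) draws 50 areas of 100–1 000 persons and
runs all five methods per area.  With one fixed seed it reproduces the
expected qualitative ranking of median overall R — SA and GA at the top,
IPF close behind, SR clearly lower, random selection last — with all
non-random methods above 0.9.

What the fixture does *not* emulate: real questionnaire universes
(tables needing rescaling rather than exact tabulation), measurement and
disclosure-control noise, genuinely multi-way interactions beyond the
sequential model, within-household correlation of characteristics, and
empty-cell severity at national scale.  Passing tests demonstrate the
machinery is correct and the methods behave as expected relative to one
another under controlled conditions — not that any particular accuracy
level carries over to real census data.

## Numerical and reproducibility notes

* All randomness flows through `numpy.random.Generator` (PCG64); every
  public sampler accepts a seed or generator.  Pipeline runs derive a
  per-area stream as `master_seed XOR crc32(area_id)` (masked below
  2³¹), so areas are independent and order-insensitive, and reruns are
  byte-identical.
* Rescaling and TAE are exact integer computations; IPF is the only
  floating-point iteration and its tolerance is expressed in persons.
* Degenerate inputs have defined behaviour: empty populations refuse
  evaluation, constant vectors refuse correlation, all-zero tables refuse
  rescaling to a positive total, non-positive temperatures are domain
  errors, and IPF names its unreachable slices.
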