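"""Combinatorial optimisation: fitness, SA mechanics, GA operators."""

import copy
import math

import numpy as np
import pytest

import microsynth as ms
from conftest import sample_from_truth


@pytest.fixture(scope="module")
def small_truth():
    return ms.generate_area(n_persons=60, seed=77, area_id="S1")


@pytest.fixture(scope="module")
def truth_pool(small_truth):
    return sample_from_truth(small_truth)


class TestFitness:
    def test_exact_candidate_scores_zero(self, schema, small_truth, truth_pool):
        cand = ms.Candidate(units=list(truth_pool.households), unit_kind="household")
        assert ms.fitness(cand, small_truth.constraints, schema) == 0

    def test_single_category_move_costs_two(self, schema, small_truth, truth_pool):
        persons = [copy.deepcopy(p) for p in small_truth.population]
        moved = persons[0]
        cats = schema.categories("T1_2")
        current = moved.categories["T1_2"]
        moved.categories["T1_2"] = next(c for c in cats if c != current)
        cand = ms.Candidate(units=persons, unit_kind="person")
        assert ms.fitness(cand, small_truth.constraints, schema) == 2

    def test_empty_candidate_scores_total_constraint_mass(
        self, schema, small_truth
    ):
        cand = ms.Candidate(units=[], unit_kind="person")
        expected = int(small_truth.constraints.concatenated(schema).sum())
        assert ms.fitness(cand, small_truth.constraints, schema) == expected


class TestAcceptanceProbability:
    def test_non_worsening_always_accepted(self):
        assert ms.acceptance_probability(0.0, 1.0) == 1.0
        assert ms.acceptance_probability(-5.0, 1.0) == 1.0

    def test_half_probability_at_t_ln2(self):
        t = 3.7
        assert ms.acceptance_probability(t * math.log(2), t) == pytest.approx(0.5)

    def test_large_delta_vanishes(self):
        assert ms.acceptance_probability(100.0, 1.0) < 1e-43

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ms.DataError):
            ms.acceptance_probability(1.0, 0.0)


class TestSimulatedAnnealing:
    def test_geometric_cooling_schedule(self, schema, small_truth, truth_pool):
        cfg = ms.SAConfig(initial_temperature=10.0, fitness_threshold=-1,
                          max_iter=5)
        _, trace = ms.simulated_annealing(
            truth_pool, small_truth.constraints, cfg,
            rng=1, schema=schema,
        )
        # temperature after 3 iterations is 0.85^3 of the initial
        np.testing.assert_allclose(trace.temperature.iloc[3], 0.614125 * 10.0)
        np.testing.assert_allclose(
            trace.temperature.to_numpy(), 10.0 * 0.85 ** np.arange(5)
        )

    def test_reaches_zero_when_truth_is_in_sample(
        self, schema, small_truth, truth_pool
    ):
        pop, trace = ms.simulated_annealing(
            truth_pool, small_truth.constraints, rng=2, schema=schema
        )
        assert trace.best_fitness.iloc[-1] == 0
        counts = ms.tally(pop.persons, schema)
        for t in schema.table_names:
            assert np.array_equal(
                counts[t], small_truth.constraints.counts_vector(schema, t)
            )

    def test_best_fitness_trace_non_increasing(self, schema, truth, sample):
        cfg = ms.SAConfig(max_iter=300)
        _, trace = ms.simulated_annealing(
            sample, truth.constraints, cfg, rng=3, schema=schema
        )
        assert (np.diff(trace.best_fitness.to_numpy()) <= 0).all()

    def test_seeded_determinism(self, schema, small_truth, truth_pool):
        cfg = ms.SAConfig(max_iter=200, fitness_threshold=-1)
        p1, t1 = ms.simulated_annealing(
            truth_pool, small_truth.constraints, cfg, rng=4, schema=schema)
        p2, t2 = ms.simulated_annealing(
            truth_pool, small_truth.constraints, cfg, rng=4, schema=schema)
        assert [p.source_person_id for p in p1.persons] == [
            p.source_person_id for p in p2.persons
        ]
        assert t1.equals(t2)

    def test_population_size_within_household_band(self, schema, truth, sample):
        cfg = ms.SAConfig(max_iter=50, fitness_threshold=-1)
        pop, _ = ms.simulated_annealing(
            sample, truth.constraints, cfg, rng=5, schema=schema
        )
        max_hh = max(h.size for h in sample.households)
        n = len(pop.persons)
        assert truth.constraints.target_n <= n < truth.constraints.target_n + max_hh


class TestTournament:
    def test_full_size_returns_global_best(self):
        rng = np.random.default_rng(0)
        out = ms.tournament_select(["a", "b", "c"], [3.0, 1.0, 2.0], 3, rng)
        assert out == "b"

    def test_size_one_is_uniform(self):
        rng = np.random.default_rng(1)
        picks = {ms.tournament_select("abc", [1, 2, 3], 1, rng) for _ in range(100)}
        assert picks == {"a", "b", "c"}

    def test_size_two_matches_order_statistic_probability(self):
        # with-replacement entrants: best of 3 wins 1 - (2/3)^2 = 5/9
        rng = np.random.default_rng(2)
        runs = 10_000
        wins = sum(
            ms.tournament_select([0, 1, 2], [1.0, 2.0, 3.0], 2, rng) == 0
            for _ in range(runs)
        )
        p = 5 / 9
        se = math.sqrt(p * (1 - p) / runs)
        assert abs(wins / runs - p) < 3 * se

    def test_invalid_size_rejected(self):
        with pytest.raises(ms.DataError):
            ms.tournament_select([1], [1.0], 0, np.random.default_rng(0))


class TestCrossoverAndMutate:
    def parents(self, truth_pool):
        hh = truth_pool.households
        a = ms.Candidate(units=list(hh[:10]), unit_kind="household")
        b = ms.Candidate(units=list(hh[10:20]), unit_kind="household")
        return a, b

    def test_rate_zero_children_equal_parents(self, truth_pool):
        a, b = self.parents(truth_pool)
        ca, cb = ms.crossover(a, b, 0.0, np.random.default_rng(0))
        assert ca.units == a.units and cb.units == b.units

    def test_rate_seven_tenths_exchanges_seven_of_ten(self, truth_pool):
        a, b = self.parents(truth_pool)
        ca, cb = ms.crossover(a, b, 0.7, np.random.default_rng(1))
        moved = sum(u in set(id(x) for x in b.units) for u in map(id, ca.units))
        assert moved == 7

    def test_multiset_union_conserved(self, truth_pool):
        a, b = self.parents(truth_pool)
        for rate in (0.3, 0.7, 1.0):
            ca, cb = ms.crossover(a, b, rate, np.random.default_rng(2))
            assert sorted(
                id(u) for u in ca.units + cb.units
            ) == sorted(id(u) for u in a.units + b.units)

    def test_mutation_counts(self, truth_pool):
        base = ms.Candidate(
            units=[truth_pool.households[0]] * 100, unit_kind="household"
        )
        out = ms.mutate(base, truth_pool, 0.05, np.random.default_rng(3))
        changed = sum(u is not base.units[0] for u in out.units)
        # exactly 5 positions redrawn (a redraw may pick household 0 again)
        assert len(out.units) == 100 and changed <= 5
        untouched = ms.mutate(base, truth_pool, 0.0, np.random.default_rng(4))
        assert untouched.units == base.units
        fully = ms.mutate(base, truth_pool, 1.0, np.random.default_rng(5))
        assert len(fully.units) == 100


class TestGeneticAlgorithm:
    def test_zero_generations_returns_best_initial(
        self, schema, small_truth, truth_pool
    ):
        cfg = ms.GAConfig(generations=0, population_count=20, tournament_size=5)
        pop, trace = ms.genetic_algorithm(
            truth_pool, small_truth.constraints, cfg, rng=6, schema=schema
        )
        assert len(trace) == 1
        assert trace.best_fitness.iloc[0] == ms.fitness(
            ms.Candidate(units=[p for p in pop.persons], unit_kind="person"),
            small_truth.constraints, schema,
        )

    def test_best_ever_not_worse_than_initial(self, schema, truth, sample):
        cfg = ms.GAConfig(generations=5, population_count=20, tournament_size=5)
        _, trace = ms.genetic_algorithm(
            sample, truth.constraints, cfg, rng=7, schema=schema
        )
        assert trace.best_fitness.iloc[-1] <= trace.best_fitness.iloc[0]
        assert (np.diff(trace.best_fitness.to_numpy()) <= 0).all()

    def test_reaches_zero_on_tiny_area(self, schema):
        tiny = ms.generate_area(n_persons=30, seed=501, area_id="T30")
        pool = sample_from_truth(tiny)
        pop, trace = ms.genetic_algorithm(pool, tiny.constraints, rng=8,
                                          schema=schema)
        assert trace.best_fitness.iloc[-1] == 0

    def test_elitism_keeps_best_in_every_generation(self, schema, truth, sample):
        cfg = ms.GAConfig(
            generations=6, population_count=20, tournament_size=5, elitism=True
        )
        _, trace = ms.genetic_algorithm(
            sample, truth.constraints, cfg, rng=11, schema=schema
        )
        # the generation best can never drift above the best-ever candidate
        assert (trace.gen_best.to_numpy() == trace.best_fitness.to_numpy()).all()

    def test_seeded_determinism(self, schema, small_truth, truth_pool):
        cfg = ms.GAConfig(generations=3, population_count=10, tournament_size=3)
        p1, t1 = ms.genetic_algorithm(
            truth_pool, small_truth.constraints, cfg, rng=9, schema=schema)
        p2, t2 = ms.genetic_algorithm(
            truth_pool, small_truth.constraints, cfg, rng=9, schema=schema)
        assert [p.source_person_id for p in p1.persons] == [
            p.source_person_id for p in p2.persons
        ]
        assert t1.equals(t2)


class TestRandomBaseline:
    def test_single_household_sample_gives_replicas(self, schema):
        area = ms.generate_area(n_persons=12, seed=88, area_id="R1")
        h = ms.HouseholdRecord("h0", [
            ms.PersonRecord("p0", "h0", dict(area.population[0].categories))
        ])
        pool = ms.MicrodataSample(households=[h], persons=h.members)
        pop = ms.random_baseline(pool, area.constraints, rng=1, schema=schema)
        assert all(p.source_person_id == "p0" for p in pop.persons)

    def test_seeded_determinism(self, schema, truth, sample):
        a = ms.random_baseline(sample, truth.constraints, rng=2, schema=schema)
        b = ms.random_baseline(sample, truth.constraints, rng=2, schema=schema)
        assert [p.source_person_id for p in a.persons] == [
            p.source_person_id for p in b.persons
        ]
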