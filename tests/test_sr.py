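"""Synthetic reconstruction: conditionals, fallback, population synthesis."""

import numpy as np
import pytest

import microsynth as ms
from microsynth.sr import _choose_first_table
from conftest import make_person


@pytest.fixture(scope="module")
def toy_schema():
    return ms.CategorySchema(
        tables=(
            ("SEX", ("SEX_M", "SEX_F")),
            ("EDU", ("EDU_LO", "EDU_HI")),
            ("HH", ("HH_1", "HH_2")),
        ),
        resident_table="HH",
    )


def toy_sample(toy_schema, triples):
    persons = [
        make_person(toy_schema, t, pid=f"p{i}", hid=f"h{i}")
        for i, t in enumerate(triples)
    ]
    hhs = [ms.HouseholdRecord(p.household_id, [p]) for p in persons]
    return ms.MicrodataSample(households=hhs, persons=persons)


def brute_conditional(sample, fixed, target, schema):
    cats = schema.categories(target)
    matches = [
        p for p in sample.persons
        if all(p.categories[t] == c for t, c in fixed)
    ]
    counts = np.array(
        [sum(p.categories[target] == c for p in matches) for c in cats],
        dtype=float,
    )
    return counts / counts.sum()


class TestConditionalDistribution:
    def test_unconditional_is_marginal(self, toy_schema):
        s = toy_sample(toy_schema, [
            ("SEX_M", "EDU_LO", "HH_1"),
            ("SEX_M", "EDU_HI", "HH_1"),
            ("SEX_F", "EDU_HI", "HH_2"),
            ("SEX_F", "EDU_HI", "HH_1"),
        ])
        q = ms.ConditionalQuery(fixed=(), target_table="SEX")
        np.testing.assert_allclose(
            ms.conditional_distribution(s, q, toy_schema), [0.5, 0.5]
        )

    def test_degenerate_conditional(self, toy_schema):
        # every woman in the survey holds the higher qualification
        s = toy_sample(toy_schema, [
            ("SEX_F", "EDU_HI", "HH_1"),
            ("SEX_F", "EDU_HI", "HH_2"),
            ("SEX_M", "EDU_LO", "HH_1"),
        ])
        q = ms.ConditionalQuery(fixed=(("SEX", "SEX_F"),), target_table="EDU")
        np.testing.assert_allclose(
            ms.conditional_distribution(s, q, toy_schema), [0.0, 1.0]
        )

    def test_empty_cell_drops_last_condition(self, toy_schema):
        s = toy_sample(toy_schema, [
            ("SEX_M", "EDU_LO", "HH_1"),
            ("SEX_M", "EDU_HI", "HH_2"),
            ("SEX_F", "EDU_LO", "HH_2"),
        ])
        # no male in HH_2 with EDU_LO -> falls back to P(HH | SEX_M)
        q = ms.ConditionalQuery(
            fixed=(("SEX", "SEX_M"), ("EDU", "EDU_LO"), ),
            target_table="HH",
        )
        full = ms.conditional_distribution(s, q, toy_schema)
        np.testing.assert_allclose(
            full, brute_conditional(s, [("SEX", "SEX_M"), ("EDU", "EDU_LO")],
                                    "HH", toy_schema)
        )
        # now force an empty cell: condition on a combination absent entirely
        q2 = ms.ConditionalQuery(
            fixed=(("SEX", "SEX_F"), ("EDU", "EDU_HI")),
            target_table="HH",
        )
        reduced = brute_conditional(s, [("SEX", "SEX_F")], "HH", toy_schema)
        np.testing.assert_allclose(
            ms.conditional_distribution(s, q2, toy_schema), reduced
        )

    def test_target_in_fixed_rejected(self):
        with pytest.raises(ms.SchemaError):
            ms.ConditionalQuery(fixed=(("SEX", "SEX_F"),), target_table="SEX")

    def test_tensor_model_matches_filter_and_count(self, schema, sample):
        model = ms.ConditionalModel(sample, schema)
        rng = np.random.default_rng(17)
        persons = sample.persons
        for _ in range(20):
            p = persons[rng.integers(len(persons))]
            tables = list(schema.table_names)
            rng.shuffle(tables)
            k = int(rng.integers(0, 4))
            fixed = tuple((t, p.categories[t]) for t in tables[:k])
            target = tables[k]
            q = ms.ConditionalQuery(fixed=fixed, target_table=target)
            np.testing.assert_allclose(
                model.query(q),
                ms.conditional_distribution(sample, q, schema),
                atol=1e-12,
            )


class TestSynthesizePerson:
    def test_degenerate_marginal(self, toy_schema):
        s = toy_sample(toy_schema, [
            ("SEX_M", "EDU_LO", "HH_1"), ("SEX_F", "EDU_HI", "HH_2"),
        ])
        constraints = ms.AreaConstraints(
            area_id="A", target_n=4,
            tables={
                "SEX": {"SEX_M": 4, "SEX_F": 0},
                "EDU": {"EDU_LO": 2, "EDU_HI": 2},
                "HH": {"HH_1": 2, "HH_2": 2},
            },
        )
        model = ms.ConditionalModel(s, toy_schema)
        running = {t: np.zeros(len(toy_schema.categories(t)))
                   for t in toy_schema.table_names}
        policy = ms.SRPolicy(base_order=("SEX", "EDU", "HH"))
        p = ms.synthesize_person(
            constraints, running, model, policy, np.random.default_rng(0)
        )
        assert p.categories["SEX"] == "SEX_M"

    def test_single_record_sample_clones_it(self, toy_schema):
        s = toy_sample(toy_schema, [("SEX_F", "EDU_HI", "HH_2")])
        constraints = ms.AreaConstraints(
            area_id="A", target_n=3,
            tables={
                "SEX": {"SEX_M": 0, "SEX_F": 3},
                "EDU": {"EDU_LO": 0, "EDU_HI": 3},
                "HH": {"HH_1": 0, "HH_2": 3},
            },
        )
        pop = ms.synthesize_population_sr(
            constraints, s, rng=1, schema=toy_schema
        )
        assert all(
            p.categories == {"SEX": "SEX_F", "EDU": "EDU_HI", "HH": "HH_2"}
            for p in pop.persons
        )

    def test_55_45_marginal_frequency(self, toy_schema):
        s = toy_sample(toy_schema, [
            ("SEX_M", "EDU_LO", "HH_1"), ("SEX_F", "EDU_HI", "HH_2"),
        ])
        n = 10_000
        constraints = ms.AreaConstraints(
            area_id="A", target_n=n,
            tables={
                "SEX": {"SEX_M": int(0.55 * n), "SEX_F": int(0.45 * n)},
                "EDU": {"EDU_LO": n // 2, "EDU_HI": n - n // 2},
                "HH": {"HH_1": n // 2, "HH_2": n - n // 2},
            },
        )
        model = ms.ConditionalModel(s, toy_schema)
        policy = ms.SRPolicy(base_order=("SEX", "EDU", "HH"),
                             first_draw="replace")
        rng = np.random.default_rng(2)
        running = {t: np.zeros(len(toy_schema.categories(t)))
                   for t in toy_schema.table_names}
        males = 0
        for _ in range(n):
            p = ms.synthesize_person(constraints, running, model, policy, rng)
            males += p.categories["SEX"] == "SEX_M"
        se = np.sqrt(0.55 * 0.45 / n)
        assert abs(males / n - 0.55) < 3 * se


class TestSynthesizePopulation:
    def test_size_exactness_and_valid_codes(self, schema, sample, truth):
        pop = ms.synthesize_population_sr(
            truth.constraints, sample, rng=3, schema=schema
        )
        assert len(pop.persons) == truth.constraints.target_n
        for t in schema.table_names:
            valid = set(schema.categories(t))
            assert all(p.categories[t] in valid for p in pop.persons)

    def test_depletion_fits_first_table_exactly(self, schema, sample, truth):
        policy = ms.SRPolicy(reorder="fixed", first_draw="deplete")
        pop = ms.synthesize_population_sr(
            truth.constraints, sample, policy, rng=4, schema=schema
        )
        first = policy.resolved_order(schema)[0]
        counts = ms.tally(pop.persons, schema)[first]
        assert np.array_equal(
            counts, truth.constraints.counts_vector(schema, first)
        )

    def test_seeded_determinism(self, schema, sample, truth):
        a = ms.synthesize_population_sr(truth.constraints, sample, rng=5,
                                        schema=schema)
        b = ms.synthesize_population_sr(truth.constraints, sample, rng=5,
                                        schema=schema)
        assert [p.categories for p in a.persons] == [
            p.categories for p in b.persons
        ]

    def test_zero_target_gives_empty_population(self, schema, sample):
        constraints = ms.AreaConstraints(
            area_id="Z", target_n=0,
            tables={
                t: {c: 0 for c in schema.categories(t)}
                for t in schema.table_names
            },
        )
        pop = ms.synthesize_population_sr(constraints, sample, rng=6,
                                          schema=schema)
        assert pop.persons == []

    def test_adaptive_reorder_picks_most_deviant_table(self, schema, truth):
        policy = ms.SRPolicy(reorder="adaptive")
        running = {
            t: truth.constraints.counts_vector(schema, t).astype(float) / 2
            for t in schema.table_names
        }
        # distort one table's running counts far from target
        running["T8_1"] = np.zeros_like(running["T8_1"])
        n_done = int(running["T1_1"].sum())
        chosen = _choose_first_table(
            policy, schema, running, truth.constraints, n_done
        )
        assert chosen == "T8_1"
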