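from collections import defaultdict

import pytest

import microsynth as ms


@pytest.fixture(scope="session")
def schema():
    return ms.default_schema()


@pytest.fixture(scope="session")
def small_schema():
    """A compact three-table schema for cheap unit tests."""
    return ms.CategorySchema(
        tables=(
            ("AGE", ("AGE_Y", "AGE_M", "AGE_O")),
            ("SEX", ("SEX_M", "SEX_F")),
            ("HH", ("HH_1", "HH_2")),
        ),
        resident_table="HH",
    )


@pytest.fixture(scope="session")
def sample(schema):
    """A medium synthetic survey shared across tests (800 households)."""
    return ms.generate_sample(schema, 800, seed=11)


@pytest.fixture(scope="session")
def truth(schema):
    return ms.generate_area(n_persons=250, seed=12, area_id="A1")


def sample_from_truth(truth: ms.GroundTruthArea) -> ms.MicrodataSample:
    """Repackage a ground-truth area's own households as a survey."""
    byh = defaultdict(list)
    for p in truth.population:
        byh[p.household_id].append(p)
    households = [ms.HouseholdRecord(h, m) for h, m in byh.items()]
    return ms.MicrodataSample(
        households=households, persons=list(truth.population)
    )


def make_person(schema, codes, pid="p0", hid="h0"):
    return ms.PersonRecord(
        person_id=pid,
        household_id=hid,
        categories=dict(zip(schema.table_names, codes)),
    )
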