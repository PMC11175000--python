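import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dietscore as ds

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schema():
    return ds.load_schema()


@pytest.fixture(scope="session")
def matrix():
    return ds.load_matrix()


@pytest.fixture(scope="session")
def mds_rules():
    return ds.load_mds_rules()


@pytest.fixture(scope="session")
def medilite_rules():
    return ds.load_medilite_rules()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_compliant_profile(schema, respondent_id="R1", age=25.0, administration="T0"):
    """A fully answered, schema-valid profile (favorable everywhere)."""
    return ds.extremal_profile(
        schema, ds.load_matrix(), favorable=True, respondent_id=respondent_id
    )


@pytest.fixture()
def compliant_profile(schema):
    return make_compliant_profile(schema)


def random_light_profile(schema, rng, respondent_id="R"):
    """Cheap random profile for bulk invariant checks: uniform frequencies on
    the half-serving lattice, random portions and behavior answers."""
    freq = {
        item: float(rng.integers(0, 41)) / 2.0 for item in schema.item_ids
    }
    portions = {
        item: schema.portion_labels[int(rng.integers(len(schema.portion_labels)))]
        for item in schema.item_ids
        if schema.item(item).has_portion_question
    }
    behaviors = {
        b.id: b.answers[int(rng.integers(len(b.answers)))]
        for b in schema.behavior_questions
    }
    return ds.ResponseProfile(
        respondent_id=respondent_id,
        age_years=float(rng.integers(18, 80)),
        frequencies=freq,
        portions=portions,
        behaviors=behaviors,
    )
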