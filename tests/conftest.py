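import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_world():
    """One moderate synthetic world shared across read-only tests."""
    from snailguild import synthetic_data as sd

    config = sd.default_config(n_snails_per_site=120, seed=7)
    return sd.generate_world(config)


@pytest.fixture(scope="session")
def retained_records(default_world):
    from snailguild import pipeline as pl

    retained, _ = pl.apply_filters(default_world.records)
    return retained


@pytest.fixture(scope="session")
def growth_fit(retained_records):
    from snailguild import growth_model as gm

    return gm.fit_growth(retained_records)
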