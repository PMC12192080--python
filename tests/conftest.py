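import numpy as np
import pytest

from pyroclock import (
    Cohort,
    GeneratorConfig,
    MethylationProfile,
    SITE_KEYS,
    generate_training_cohort,
)


def make_profile(sample_id, age, values, **clinical):
    """Profile helper: ``values`` is a sequence in canonical site order or a dict."""
    if not isinstance(values, dict):
        values = dict(zip(SITE_KEYS, values))
    return MethylationProfile(sample_id, age, values, **clinical)


@pytest.fixture
def tiny_cohort():
    """Three samples at ages 10/30/50 with plausible panel values."""
    rows = [
        ("s1", 10, (2.2, 17.7, 11.4, 82.2, 8.1, 30.1)),
        ("s2", 30, (4.9, 27.5, 21.6, 66.7, 20.2, 59.8)),
        ("s3", 50, (5.0, 45.8, 20.7, 40.4, 25.0, 66.2)),
    ]
    return Cohort([make_profile(s, a, v) for s, a, v in rows], label="tiny")


@pytest.fixture(scope="session")
def training_cohort():
    """Synthetic training cohort in the study design: decades 10-50, 12 per decade."""
    return generate_training_cohort(
        GeneratorConfig(decades=(10, 20, 30, 40, 50), n_per_decade=12, seed=7)
    )


@pytest.fixture(scope="session")
def full_range_cohort():
    """Full 10-80 decade design (96 samples)."""
    return generate_training_cohort(GeneratorConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
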