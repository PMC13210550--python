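import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from bromeval import synthetic_data as sd

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def schema():
    return sd.default_schema()


@pytest.fixture(scope="session")
def trial_spec():
    return sd.default_trial_spec()


@pytest.fixture(scope="session")
def trial_table(trial_spec):
    return sd.generate_trial(trial_spec, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def zero_effect_spec(baseline=10.0, residual_sd=0.0, block_sd=0.0, **overrides):
    """A minimal spec with all effects zero, for degenerate-case tests."""
    indicators = list(sd.INDICATORS)
    base = {i: baseline for i in indicators}
    spec = dict(
        baseline=base,
        genotype_effects={g: {i: 0.0 for i in indicators} for g in ("A", "B", "C")},
        year_effects={y: {i: 0.0 for i in indicators} for y in ("y1", "y2")},
        interaction_effects={},
        residual_sd={i: residual_sd for i in indicators},
        block_sd=block_sd,
        n_blocks=2,
    )
    spec.update(overrides)
    return sd.EffectSpec(**spec)


@pytest.fixture()
def make_zero_spec():
    return zero_effect_spec
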