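import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import multiroi as mr

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def atlas():
    return mr.builtin_atlas()


@pytest.fixture(scope="session")
def small_cohort():
    """A small effect-free cohort for I/O and plumbing tests."""
    cohort, _ = mr.generate_cohort(mr.EffectSpec(n_high=6, n_low=6, seed=11))
    return cohort


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return mr.extract_features(small_cohort)


@pytest.fixture(scope="session")
def separable_cohort():
    """A cohort with huge planted effects: groups trivially separable."""
    spec = mr.EffectSpec(
        roi_effects=[(roi, m, 4.0) for roi in (5, 20) for m in ("gmv", "wmv", "thk")],
        connection_effects=[(31, 47, 1.5), (2, 11, 1.5)],
        n_high=8,
        n_low=8,
        seed=7,
    )
    cohort, _ = mr.generate_cohort(spec)
    return cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
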