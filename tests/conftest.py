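import numpy as np
import pandas as pd
import pytest

from isosub.simulate import default_params, generate_cohort


@pytest.fixture(scope="session")
def cohort_gamma():
    """Default-parameter cohort, n=1524, gamma-driven outcomes."""
    return generate_cohort(default_params(seed=1))


@pytest.fixture(scope="session")
def cohort_beta():
    """Cohort whose outcomes follow the per-hour (ISM) truth."""
    return generate_cohort(default_params(seed=7, truth_mode="beta"))


@pytest.fixture(scope="session")
def table1_base():
    """The pooled-sample arithmetic mean composition (sit, stand, step)."""
    from isosub.composition import BehaviourComposition

    return BehaviourComposition(548.0, 286.0, 107.0, 941.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
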