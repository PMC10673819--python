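import numpy as np
import pandas as pd
import pytest

from pupfast import (
    FastingThresholds,
    TrajectoryParams,
    classify_dataframe,
    default_design,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def thresholds():
    return FastingThresholds.default()


@pytest.fixture(scope="session")
def cohort():
    """Moderate default-design cohort (~380 pups), fixed seed."""
    return simulate_cohort(default_design(seed=7, n_scale=0.25))


@pytest.fixture(scope="session")
def classified(cohort, thresholds):
    return classify_dataframe(cohort, thresholds)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Full-size cohort with zero metabolite dispersion (ground truth exact)."""
    traj = TrajectoryParams(bun_cv=0.0, bhba_cv=0.0)
    return simulate_cohort(default_design(seed=11, n_scale=0.5), traj=traj)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
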