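import warnings

import numpy as np
import pytest

from ocddm import (
    NativeParams,
    SimConfig,
    simulate_dataset,
)
from ocddm.recovery import RecoveryStudyConfig, run_recovery_study

# The reference parameter setting (~30% errors) used throughout the tests.
REFERENCE = dict(v=0.5, x0=1.0, b=10.0, sigma=4.0, t_nd=0.3)


@pytest.fixture(scope="session")
def ref_params() -> NativeParams:
    return NativeParams(**REFERENCE)


@pytest.fixture(scope="session")
def ref_dataset_10k(ref_params) -> object:
    """10,000 vanilla trials at the reference setting (shared across tests)."""
    return simulate_dataset(ref_params, cfg=SimConfig(seed=101, n_trials=10_000))


@pytest.fixture(scope="session")
def ref_dataset_200(ref_params) -> object:
    return simulate_dataset(ref_params, cfg=SimConfig(seed=7, n_trials=200))


def _study(regime: str, methods, reps: int, seed: int):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_recovery_study(
            RecoveryStudyConfig(
                regime=regime, n_replications=reps, n_trials=200,
                methods=methods, seed=seed,
            )
        )


# Monte-Carlo recovery studies at 100 replications of 200 trials each; these
# are shared between the benchmark-contrast and identifiability tests.
@pytest.fixture(scope="session")
def varying_study():
    return _study("varying_drift", ("oca", "mom", "motm"), 100, 23)


@pytest.fixture(scope="session")
def collapsing_study():
    return _study("collapsing_bounds", ("oca", "mom", "motm"), 100, 23)


@pytest.fixture(scope="session")
def fixed_study():
    return _study("fixed_drift", ("oca", "mom", "motm"), 100, 23)
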