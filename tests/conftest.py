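import numpy as np
import pytest

from ssmpca import (
    SimulationConfig,
    simulate_cohort,
    cohort_mask,
    derive_pattern,
)


@pytest.fixture(scope="session")
def small_cfg():
    """Fast cohort for unit tests: 20^3 grid, 8+8 derivation, 4 validation."""
    return SimulationConfig(
        grid_shape=(20, 20, 20),
        n_controls=8,
        n_patients=8,
        n_validation=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return simulate_cohort(small_cfg)


@pytest.fixture(scope="session")
def derivation(small_cfg, small_cohort):
    """(scans, labels) of the derivation sample only."""
    scans, gt = small_cohort
    n = small_cfg.n_controls + small_cfg.n_patients
    return scans[:n], gt.group_labels[:n]


@pytest.fixture(scope="session")
def small_mask(derivation):
    scans, _ = derivation
    return cohort_mask(scans, 0.35)


@pytest.fixture(scope="session")
def small_pattern(derivation, small_mask):
    scans, labels = derivation
    pattern, basis = derive_pattern(scans, labels, small_mask)
    return pattern, basis


@pytest.fixture
def rng():
    return np.random.default_rng(42)
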