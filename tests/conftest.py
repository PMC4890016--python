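import numpy as np
import pytest

from facedcm import (
    CohortConfig,
    build_block_design,
    build_inputs,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_design():
    """One repetition per condition, 4-scan blocks: 48 scans."""
    return build_block_design(n_reps=1, block_scans=4, tr_s=1.45, n_runs=1,
                              break_scans=0, seed=7)


@pytest.fixture(scope="session")
def small_inputs(small_design):
    return build_inputs(small_design, small_design.tr_s / 8.0)


@pytest.fixture(scope="session")
def default_design():
    return build_block_design(seed=0)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two RH subjects with short sessions, all modalities generated."""
    cfg = CohortConfig(
        n_per_group=2, seed=5, groups=("RH",), n_reps=1, block_scans=10,
        n_runs=1, break_scans=0, microtime_bins=8, a_diag_sd=0.0,
        pupil_fs=100.0,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
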