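import numpy as np
import pytest

from acmgcalib import (
    CalibrationConfig,
    DistributionSpec,
    SyntheticTruthsetSpec,
    calibrate,
    generate_truthset,
)


@pytest.fixture(scope="session")
def overlapping_truthset():
    """Moderately overlapping Gaussian classes with unlabelled variants."""
    spec = SyntheticTruthsetSpec(
        benign_dist=DistributionSpec.gaussian(0.35, 0.15),
        pathogenic_dist=DistributionSpec.gaussian(0.65, 0.15),
        n_benign=60,
        n_pathogenic=60,
        n_unlabelled=30,
        seed=11,
    )
    return generate_truthset(spec)


@pytest.fixture(scope="session")
def fast_config():
    """Reduced-resample configuration keeping unit tests quick."""
    return CalibrationConfig(n_resamples=150, grid_size=512, seed=3)


@pytest.fixture(scope="session")
def calibrated_result(overlapping_truthset, fast_config):
    """One full calibration shared by tests that only inspect the output."""
    return calibrate(overlapping_truthset.table, value="score", config=fast_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
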