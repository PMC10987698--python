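import numpy as np
import pytest

from dwmrs.basis import REPORTED_METABOLITES, make_basis
from dwmrs.pipeline import PipelineConfig, run_pipeline
from dwmrs.protocol import AcquisitionProtocol


@pytest.fixture(scope="session")
def small_protocol() -> AcquisitionProtocol:
    """The study's nine b-values with reduced shot counts and grid, keeping
    the per-b SNR structure (noise is calibrated to the lowest-b average)."""
    return AcquisitionProtocol(
        b_values=(0.4, 1.5, 6.0, 7.6, 9.3, 13.3, 15.6, 20.8, 25.1),
        shots_per_b=(8, 8, 8, 8, 8, 16, 24, 24, 24),
        n_points=2048,
    )


@pytest.fixture(scope="session")
def small_basis(small_protocol):
    return make_basis(list(REPORTED_METABOLITES), small_protocol, 6.0)


@pytest.fixture(scope="session")
def small_cohort_result(small_protocol):
    """One fully processed small cohort at the default study configuration."""
    return run_pipeline(PipelineConfig(seed=7, protocol=small_protocol))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
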