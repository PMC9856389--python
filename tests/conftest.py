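import numpy as np
import pytest

from fcmst import BandDefinition, CouplingSpec, lag_matrix_from_offsets
from fcmst.experiments import experiment_run_config
from fcmst.pipeline import cohort_metric_table
from fcmst.synthetic import generate_cohort

ALPHA = BandDefinition("alpha", 8.0, 12.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_coupling(n_channels=2, offsets=(0.0, 0.0), jitter_sd=0.0,
                  gain=0.0, topography=None, noise_sd=0.0, band=ALPHA):
    return CouplingSpec(
        n_channels=n_channels,
        band=band,
        lag_matrix=lag_matrix_from_offsets(offsets),
        jitter_sd=jitter_sd,
        common_source_gain=gain,
        source_topography=topography,
        noise_sd=noise_sd,
    )


@pytest.fixture(scope="session")
def tiny_metric_table():
    """Subject-level metrics of a small two-group cohort (shared, read-only)."""
    cfg = experiment_run_config(
        seed=11, n_per_group=4, n_channels=8,
        group_effect={"common_source_gain": 0.8},
    )
    return cfg, cohort_metric_table(generate_cohort(cfg.cohort_spec()), cfg)
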