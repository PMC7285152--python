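import numpy as np
import pytest

import gdose
from gdose.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def geom():
    return gdose.DetectorGeometry()


@pytest.fixture(scope="session")
def grid():
    return gdose.EnergyGrid.linear()


@pytest.fixture(scope="session")
def h_table():
    return gdose.load_default_h_table()


@pytest.fixture(scope="session")
def default_result():
    """One full default pipeline run shared by the slower tests."""
    return run_pipeline(PipelineConfig(seed=1))


@pytest.fixture(scope="session")
def small_grid():
    return gdose.EnergyGrid.linear(n_channels=200, e_min=0.0, e_max=3100.0)


def small_config(**overrides):
    """A reduced configuration for fast pipeline-level tests."""
    base = dict(
        n_channels=250,
        n_calibration=14,
        n_test=8,
        gp_stride=16,
        n_samples=40,
        gp_n_starts=4,
        seed=3,
    )
    base.update(overrides)
    return PipelineConfig(**base)
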