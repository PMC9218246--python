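import numpy as np
import pytest

from dissectflow import PhantomConfig, generate_phantom
from dissectflow.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def noiseless_config():
    """Straight-tube phantom without noise, jet or eddy fields (64^3, 20 phases)."""
    return PhantomConfig(noise_sigma_ms=0.0, tear_jet_speed_ms=0.0)


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_config):
    series, truth = generate_phantom(noiseless_config)
    return noiseless_config, series, truth


@pytest.fixture(scope="session")
def noiseless_pipeline(noiseless_config, tmp_path_factory):
    """Full pipeline run on the clean phantom (no corruption, no preprocessing)."""
    cfg = RunConfig(
        phantom=noiseless_config,
        corrupt=False,
        preprocess=False,
        out_dir=str(tmp_path_factory.mktemp("noiseless_run")),
    )
    return cfg, run_pipeline(cfg)


@pytest.fixture()
def small_phantom_config():
    """Cheap phantom for pipeline-level tests."""
    return PhantomConfig(
        grid_shape=(40, 40, 32),
        voxel_size_mm=2.5,
        n_phases=10,
        tl_radius_mm=9.0,
        fl_radius_mm=12.0,
        vessel_length_mm=80.0,
        noise_sigma_ms=0.0,
        tear_jet_speed_ms=0.0,
    )
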