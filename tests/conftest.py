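import numpy as np
import pytest

from tensiopipe import cgtension as cg
from tensiopipe import synthdata as sd

CONTROL_PARAMS = dict(
    forces=(2.0, 6.0, 12.5, 18.0, 25.0),
    intercept_a0=190.0,
    slope_beta=-4.7,
    width_b=12.0,
)


@pytest.fixture(scope="session")
def control_records():
    cfg = sd.ActivationGenConfig(n_per_force=44, seed=11, **CONTROL_PARAMS)
    return sd.generate_critical_pressures(cfg)


@pytest.fixture(scope="session")
def coarse_cg_config():
    return dict(
        patch_radius_um=3.0,
        edge_length_um=0.2,
        spring_k=10.0,
        pre_strain=0.02,
        jitter=0.05,
        seed=1,
    )


@pytest.fixture(scope="session")
def anchored_system(coarse_cg_config):
    cfg = cg.CgConfig(anchor_spacing_um=0.3, anchor_k=5.0, **coarse_cg_config)
    return cg.build_system(cfg)


@pytest.fixture(scope="session")
def free_system(coarse_cg_config):
    cfg = cg.CgConfig(anchor_spacing_um=None, **coarse_cg_config)
    return cg.build_system(cfg)


@pytest.fixture(scope="session")
def noiseless_wave_movie():
    cfg = sd.CalciumMovieConfig(
        shape=(80, 100, 100), pixel_size_um=0.5, origin=(50, 50),
        wave_speed_um_s=10.0, onset_frame=10, noise_sd=0.0, seed=1,
    )
    green, _ = sd.generate_calcium_movie(cfg)
    return cfg, green


def logistic_cdf(x, a, b):
    return 1.0 / (1.0 + np.exp(-(np.asarray(x, dtype=float) - a) / b))
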