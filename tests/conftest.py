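import numpy as np
import pytest

from gvscan.config import AcquisitionConfig
from gvscan.simulate import SceneTruth, simulate_acquisition


@pytest.fixture
def small_invivo_config():
    """Fast 1+7-frame GI-mode schedule on a small image grid."""
    return AcquisitionConfig(
        transducer_id="L22-14vX", mode="burst_star_invivo",
        n_low_frames=1, n_high_frames=7, low_voltage=1.6, high_voltage=20.0,
        axial_spacing=0.1, lateral_spacing=0.1,
    )


@pytest.fixture
def small_invitro_config():
    return AcquisitionConfig(
        transducer_id="L22-14v", mode="burst_invitro",
        n_low_frames=2, n_high_frames=6, low_voltage=1.6, high_voltage=25.0,
        axial_spacing=0.1, lateral_spacing=0.1,
    )


@pytest.fixture
def point_scene():
    """Noise- and speckle-free scene with a single gas-vesicle pixel."""
    gv = np.zeros((32, 24))
    gv[10, 12] = 2.0
    return SceneTruth(
        gv_map=gv, background_map=np.ones((32, 24)),
        speckle_scale=0.0, noise_sd=0.0, seed=7,
    )


@pytest.fixture
def point_stack(small_invivo_config, point_scene):
    return simulate_acquisition(small_invivo_config, point_scene)
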