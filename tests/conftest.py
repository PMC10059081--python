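import numpy as np
import pytest

from canopytherm import (
    DriftModel,
    ProtocolConfig,
    SceneConfig,
    generate_scene,
    generate_session,
    truth_registration,
)


@pytest.fixture
def small_scene_config() -> SceneConfig:
    """A desk-scale scene: 120x160 visible over a 30x40 thermal grid."""
    return SceneConfig(
        image_size_visible=(120, 160),
        grid_size_thermal=(30, 40),
        cover_fraction=0.35,
    )


@pytest.fixture
def noiseless_scene_config() -> SceneConfig:
    return SceneConfig(
        image_size_visible=(120, 160),
        grid_size_thermal=(30, 40),
        cover_fraction=0.35,
        canopy_spatial_sd_C=0.0,
        sensor_noise_sd_C=0.0,
    )


@pytest.fixture
def short_protocol() -> ProtocolConfig:
    return ProtocolConfig(n_series=3, n_repetitions=5)


@pytest.fixture
def small_session(small_scene_config, short_protocol):
    return generate_session(
        small_scene_config, DriftModel(), short_protocol, seed=11
    )
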