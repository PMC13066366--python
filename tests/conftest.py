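import numpy as np
import pytest

from agballoc.scene import (
    ScenarioConfig,
    TypeParams,
    generate_scene,
    sample_surveys,
)


@pytest.fixture
def flat_config():
    """Single type, no noise, no forcing: H=20 cm, C=0.5, rho=3 everywhere."""
    return ScenarioConfig(
        grid_rows=8,
        grid_cols=8,
        type_params={1: TypeParams(0.12, 0.82, 3.0, 20.0, 0.5)},
        seed=11,
    )


@pytest.fixture
def flat_scene(flat_config):
    return generate_scene(flat_config)


@pytest.fixture
def heterogeneous_config():
    """Noise-free but spatially and temporally varying (two types, driver
    forcing, static fields) so cover/height/NDVI all vary."""
    return ScenarioConfig(
        grid_rows=20,
        grid_cols=20,
        type_params={
            1: TypeParams(0.10, 0.80, 11.0, 24.0, 0.55),
            2: TypeParams(0.14, 0.78, 9.0, 12.0, 0.35),
        },
        driver_trends={"Ra": -0.02, "Pr": 0.03, "Ta": 0.05, "Ca": 0.05, "Gp": 0.04},
        height_response={"Ra": 0.46, "Pr": 0.34, "Ta": -0.69, "Ca": 0.23, "Gp": -0.46},
        cover_response={"Ra": 0.0, "Pr": 0.04, "Ta": -0.01, "Ca": 0.03, "Gp": 0.005},
        driver_field_sigma=0.5,
        cover_base_field_sigma=0.05,
        height_base_field_sigma=1.5,
        smooth_sigma=3.0,
        seed=21,
    )


@pytest.fixture
def heterogeneous_scene(heterogeneous_config):
    return generate_scene(heterogeneous_config)


@pytest.fixture
def noisy_surveys(heterogeneous_scene):
    from agballoc.scene import SurveyNoise

    return sample_surveys(
        heterogeneous_scene, 400, noise=SurveyNoise(3.0, 0.02, 1.0), seed=5
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
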