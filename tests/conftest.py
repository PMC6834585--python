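import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from scquant.metrics import QuantConfig, quantify_model
from scquant.model import ElementRegion, Polyline, SCModel, ScaleInfo
from scquant.synthetic import GeneratorConfig, generate_cohort, generate_sc, zero_noise_config

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

# generator notes (quota adjustments etc.) are expected in several scenarios
warnings.filterwarnings("ignore", module="scquant.synthetic")


def make_slab(role, y_center, y_half, x_half=200.0, z_half=100.0, points=None):
    return ElementRegion(
        role=role,
        kind="slab",
        points=points,
        delta_nm=4.0,
        center=np.array([0.0, y_center, 0.0]),
        axes=np.eye(3),
        half_extents=np.array([x_half, y_half, z_half]),
    )


@pytest.fixture
def tiny_model():
    """Handcrafted 2-TF model with 4-point element clouds (units px)."""
    le_left = ElementRegion(
        role="LE_left", kind="point_cloud", delta_nm=4.0,
        points=np.array([[0, -60, 0], [10, -60, 0], [0, -65, 0], [10, -65, 0]], float),
    )
    le_right = ElementRegion(
        role="LE_right", kind="point_cloud", delta_nm=4.0,
        points=np.array([[0, 60, 0], [10, 60, 0], [0, 65, 0], [10, 65, 0]], float),
    )
    ce = ElementRegion(
        role="CE", kind="point_cloud", delta_nm=4.0,
        points=np.array([[0, -5, 0], [10, -5, 0], [0, 5, 0], [10, 5, 0]], float),
    )
    tfs = [
        Polyline(np.array([[2.0, -70.0, 0.0], [2.5, -40.0, 0.0], [3.0, -2.0, 0.0]]), "a"),
        Polyline(np.array([[7.0, 3.0, 1.0], [6.0, 38.0, 0.5], [5.0, 72.0, 0.0]]), "b"),
    ]
    return SCModel(le_left=le_left, le_right=le_right, ce=ce, tfs=tfs,
                   scale=ScaleInfo(), units="px", source="tiny")


@pytest.fixture(scope="session")
def zero_noise():
    model, truth = generate_sc(zero_noise_config(), seed=1)
    return model, truth


@pytest.fixture(scope="session")
def default_cohort():
    """Six-tomogram cohort at default geometry, ~500 TFs, master seed 1."""
    cfg = GeneratorConfig(sc_length_nm=1055.0)
    return generate_cohort(cfg, 6, seed=1)


@pytest.fixture(scope="session")
def default_cohort_results(default_cohort):
    return [quantify_model(model, QuantConfig()) for model, _ in default_cohort]
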