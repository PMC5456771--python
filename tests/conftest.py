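import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tracheamech import MODELS, HyperelasticParams, cauchy_stress
from tracheamech.tensile_processing import StressStretchCurve, uniform_grid

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# Published Yeoh / Mooney-Rivlin coefficients per tissue (MPa)
TABLE_YEOH = {
    "cartilage": (3.583, -2.534, 12.020),
    "smooth_muscle": (0.063, 0.394, -0.171),
    "connective": (0.257, 0.483, -0.148),
}
TABLE_MOONEY = {
    "cartilage": (2.766, 0.770),
    "smooth_muscle": (1.164, -1.223),
    "connective": (1.836, -1.775),
}
LAMBDA_MAX = {"cartilage": 1.2, "smooth_muscle": 1.5, "connective": 1.5}


def random_params(model_id: str, rng: np.random.Generator) -> HyperelasticParams:
    """Coefficient draws spanning the magnitudes seen in tracheal fits."""
    n = MODELS[model_id]
    coeffs = rng.uniform(0.05, 5.0, size=n) * rng.choice([1.0, -1.0], size=n)
    if model_id in ("fung", "humphrey", "veronda_westmann"):
        coeffs[1] = rng.uniform(0.2, 4.0)
    if model_id == "ogden":
        coeffs[1::2] = rng.uniform(0.5, 6.0, size=3) * rng.choice(
            [1.0, -1.0], size=3
        )
    return HyperelasticParams(model_id, tuple(coeffs))


def reference_curve(tissue: str, model: str = "yeoh") -> StressStretchCurve:
    """Noiseless stress-stretch curve reconstructed from the published
    coefficients on the tissue's standard grid."""
    coeffs = TABLE_YEOH[tissue] if model == "yeoh" else TABLE_MOONEY[tissue]
    params = HyperelasticParams(model, coeffs)
    grid = uniform_grid(LAMBDA_MAX[tissue])
    return StressStretchCurve(
        stretch=grid,
        stress=np.asarray(cauchy_stress(params, grid)),
        tissue=tissue,
    )


@pytest.fixture(scope="session")
def smooth_muscle_curve():
    return reference_curve("smooth_muscle")


@pytest.fixture(scope="session")
def connective_curve():
    return reference_curve("connective")


@pytest.fixture(scope="session")
def cartilage_curve():
    return reference_curve("cartilage")
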