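"""Isotropic incompressible hyperelastic models under uniaxial tension.

Seven strain-energy functions W (Mooney-Rivlin, Yeoh, Fung, Neo-Hookean,
Humphrey, Ogden, Veronda-Westmann) with their closed-form uniaxial Cauchy
stress expressions, derived from

    sigma_1 = lambda_1 dW/dlambda_1 - lambda_3 dW/dlambda_3
            = 2 (lambda^2 - 1/lambda) (dW/dI1 + (1/lambda) dW/dI2)

for an incompressible material (lambda_2 = lambda_3 = lambda^(-1/2),
I3 = 1).  A central finite-difference evaluation of the first identity on
W(lambda_1, lambda_2, lambda_3) serves as an independent oracle for the
closed forms.

Stress-like coefficients are in MPa (so stresses computed from forces in N
and areas in mm^2 need no conversion); exponents are dimensionless.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MODELS",
    "StretchState",
    "HyperelasticParams",
    "invariants_from_uniaxial_stretch",
    "deformation_gradient_uniaxial",
    "strain_energy",
    "cauchy_stress",
    "cauchy_stress_fd_oracle",
    "initial_tangent_modulus",
]

# Exponent arguments a2*(I1-3) are clipped here before exp() to avoid
# overflow during wide multistart searches.
EXP_CLIP = 50.0

#: model id -> number of coefficients
MODELS: dict[str, int] = {
    "mooney_rivlin": 2,
    "yeoh": 3,
    "fung": 2,
    "neo_hookean": 1,
    "humphrey": 2,
    "ogden": 6,
    "veronda_westmann": 2,
}

#: models whose second coefficient is an exponent and must be nonzero
_EXPONENTIAL_MODELS = frozenset({"fung", "humphrey", "veronda_westmann"})


@dataclass(frozen=True)
class StretchState:
    """Uniaxial incompressible kinematic state at stretch lambda."""

    lambda_: float
    lambda2: float
    lambda3: float
    I1: float
    I2: float
    I3: float


@dataclass(frozen=True)
class HyperelasticParams:
    """A model id plus its ordered coefficient vector a1..an."""

    model_id: str
    coeffs: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.model_id not in MODELS:
            raise ValueError(
                f"unknown model {self.model_id!r}; known: {sorted(MODELS)}"
            )
        coeffs = tuple(float(c) for c in self.coeffs)
        object.__setattr__(self, "coeffs", coeffs)
        n = MODELS[self.model_id]
        if len(coeffs) != n:
            raise ValueError(
                f"{self.model_id} takes {n} coefficients, got {len(coeffs)}"
            )
        if self.model_id in _EXPONENTIAL_MODELS and coeffs[1] == 0.0:
            raise ValueError(f"{self.model_id} requires a2 != 0")
        if self.model_id == "ogden":
            for n_term in range(3):
                mu, alpha = coeffs[2 * n_term], coeffs[2 * n_term + 1]
                if mu != 0.0 and alpha == 0.0:
                    raise ValueError(
                        "ogden term with nonzero modulus needs nonzero exponent"
                    )

    def to_json(self) -> str:
        return json.dumps({"model": self.model_id, "coeffs": list(self.coeffs)})

    @classmethod
    def from_json(cls, text: str) -> "HyperelasticParams":
        obj = json.loads(text)
        return cls(obj["model"], tuple(obj["coeffs"]))


def _check_stretch(lambda_) -> None:
    if np.any(np.asarray(lambda_) <= 0):
        raise ValueError("stretch must be positive")


def invariants_from_uniaxial_stretch(lambda_: float) -> StretchState:
    """Kinematics of incompressible uniaxial tension at stretch lambda.

    I1 = lambda^2 + 2/lambda, I2 = 2 lambda + 1/lambda^2, I3 = 1;
    transverse stretches lambda^(-1/2).
    """
    _check_stretch(lambda_)
    lam = float(lambda_)
    lat = lam ** -0.5
    return StretchState(
        lambda_=lam,
        lambda2=lat,
        lambda3=lat,
        I1=lam**2 + 2.0 / lam,
        I2=2.0 * lam + 1.0 / lam**2,
        I3=1.0,
    )


def deformation_gradient_uniaxial(lambda_: float) -> np.ndarray:
    """diag(lambda, lambda^-1/2, lambda^-1/2); det F = 1 (volume preserved)."""
    _check_stretch(lambda_)
    lam = float(lambda_)
    return np.diag([lam, lam**-0.5, lam**-0.5])


def _invariants_general(l1, l2, l3):
    I1 = l1**2 + l2**2 + l3**2
    I2 = l1**2 * l2**2 + l2**2 * l3**2 + l1**2 * l3**2
    return I1, I2


def _energy_general(params: HyperelasticParams, l1, l2, l3):
    """W as a function of three principal stretches (no incompressibility
    substitution) so it can be differentiated w.r.t. each stretch."""
    a = params.coeffs
    I1, I2 = _invariants_general(l1, l2, l3)
    m = params.model_id
    if m == "neo_hookean":
        return a[0] * (I1 - 3.0)
    if m == "mooney_rivlin":
        return a[0] * (I1 - 3.0) + a[1] * (I2 - 3.0)
    if m == "yeoh":
        x = I1 - 3.0
        return a[0] * x + a[1] * x**2 + a[2] * x**3
    if m == "fung":
        z = np.clip(a[1] * (I1 - 3.0), -EXP_CLIP, EXP_CLIP)
        return a[0] / (2.0 * a[1]) * (np.exp(z) - 1.0)
    if m == "humphrey":
        z = np.clip(a[1] * (I1 - 3.0), -EXP_CLIP, EXP_CLIP)
        return a[0] * (np.exp(z) - 1.0)
    if m == "veronda_westmann":
        z = np.clip(a[1] * (I1 - 3.0), -EXP_CLIP, EXP_CLIP)
        return a[0] * (np.exp(z) - 1.0) - a[0] * a[1] / 2.0 * (I2 - 3.0)
    if m == "ogden":
        w = 0.0
        for n in range(3):
            mu, alpha = a[2 * n], a[2 * n + 1]
            if mu == 0.0:
                continue
            w = w + (mu / alpha) * (l1**alpha + l2**alpha + l3**alpha - 3.0)
        return w
    raise AssertionError(m)


def strain_energy(params: HyperelasticParams, state: StretchState) -> float:
    """Strain-energy density W (MPa) at a uniaxial stretch state; W(1) = 0."""
    return float(
        _energy_general(params, state.lambda_, state.lambda2, state.lambda3)
    )


def cauchy_stress(params: HyperelasticParams, lambda_):
    """Closed-form uniaxial Cauchy stress sigma (MPa); vectorized in lambda.

    All forms share the kinematic prefactor 2(lambda^2 - 1/lambda) except
    Fung (factor 1) and Ogden (stretch-based).
    """
    _check_stretch(lambda_)
    lam = np.asarray(lambda_, dtype=float)
    a = params.coeffs
    I1 = lam**2 + 2.0 / lam
    pre = 2.0 * (lam**2 - 1.0 / lam)
    m = params.model_id
    if m == "neo_hookean":
        sig = a[0] * pre
    elif m == "mooney_rivlin":
        sig = pre * (a[0] + a[1] / lam)
    elif m == "yeoh":
        x = I1 - 3.0
        sig = pre * (a[0] + 2.0 * a[1] * x + 3.0 * a[2] * x**2)
    elif m == "fung":
        z = np.clip(a[1] * (I1 - 3.0), -EXP_CLIP, EXP_CLIP)
        sig = a[0] * (lam**2 - 1.0 / lam) * np.exp(z)
    elif m == "humphrey":
        z = np.clip(a[1] * (I1 - 3.0), -EXP_CLIP, EXP_CLIP)
        sig = a[0] * a[1] * pre * np.exp(z)
    elif m == "veronda_westmann":
        z = np.clip(a[1] * (I1 - 3.0), -EXP_CLIP, EXP_CLIP)
        sig = a[0] * a[1] * pre * (np.exp(z) - 1.0 / (2.0 * lam))
    elif m == "ogden":
        sig = np.zeros_like(lam, dtype=float)
        loglam = np.log(lam)
        for n in range(3):
            mu, alpha = a[2 * n], a[2 * n + 1]
            if mu == 0.0:
                continue
            # lam**alpha via exp(alpha ln lam), clipped against overflow
            # during wide optimizer excursions
            sig = sig + mu * (
                np.exp(np.clip(alpha * loglam, -EXP_CLIP, EXP_CLIP))
                - np.exp(np.clip(-alpha / 2.0 * loglam, -EXP_CLIP, EXP_CLIP))
            )
    else:  # pragma: no cover
        raise AssertionError(m)
    if np.isscalar(lambda_) or np.ndim(lambda_) == 0:
        return float(sig)
    return sig


def cauchy_stress_fd_oracle(
    params: HyperelasticParams, lambda_: float, step: float = 1e-6
) -> float:
    """Brute-force uniaxial Cauchy stress from central finite differences.

    Evaluates sigma_1 = lambda_1 dW/dlambda_1 - lambda_3 dW/dlambda_3 on
    W(lambda_1, lambda_2, lambda_3), independently of the closed forms in
    :func:`cauchy_stress`.
    """
    _check_stretch(lambda_)
    lam = float(lambda_)
    lat = lam ** -0.5

    def w(l1, l3):
        return _energy_general(params, l1, lat, l3)

    dw_dl1 = (w(lam + step, lat) - w(lam - step, lat)) / (2.0 * step)
    dw_dl3 = (w(lam, lat + step) - w(lam, lat - step)) / (2.0 * step)
    return lam * dw_dl1 - lat * dw_dl3


def initial_tangent_modulus(params: HyperelasticParams) -> float:
    """Small-strain tangent d(sigma)/d(lambda) at lambda = 1 (MPa).

    Can be negative for non-physical coefficient sets (e.g. Mooney-Rivlin
    with a1 + a2 < 0), which callers may flag.
    """
    a = params.coeffs
    m = params.model_id
    if m == "neo_hookean":
        return 6.0 * a[0]
    if m == "yeoh":
        return 6.0 * a[0]
    if m == "mooney_rivlin":
        return 6.0 * (a[0] + a[1])
    if m == "fung":
        return 3.0 * a[0]
    if m == "humphrey":
        return 6.0 * a[0] * a[1]
    if m == "veronda_westmann":
        return 3.0 * a[0] * a[1]
    if m == "ogden":
        return 1.5 * math.fsum(a[2 * n] * a[2 * n + 1] for n in range(3))
    raise AssertionError(m)  # pragma: no cover
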