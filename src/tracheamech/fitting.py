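"""Least-squares identification of hyperelastic coefficients.

Each model's uniaxial Cauchy stress is fitted to a stress-stretch curve by
Levenberg-Marquardt from multiple starting points (one deterministic
heuristic seeded from the curve's small-strain modulus, the rest drawn from
a seeded log-uniform spread), models are ranked by the coefficient of
determination R^2, and the quasi-linear Young's modulus of cartilage is
extracted by ordinary least squares on engineering strain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .constitutive import MODELS, HyperelasticParams, cauchy_stress
from .tensile_processing import StressStretchCurve

__all__ = [
    "FitResult",
    "ModelRanking",
    "r_squared",
    "fit_model",
    "fit_all_models",
    "linear_modulus",
]

#: rank resolution for R^2 ties (printed-table precision)
R2_TIE_RESOLUTION = 1e-3

_N_STARTS_DEFAULT = 16

#: which coefficient positions are exponents (dimensionless), per model
_EXPONENT_SLOTS = {
    "fung": (1,),
    "humphrey": (1,),
    "veronda_westmann": (1,),
    "ogden": (1, 3, 5),
}


@dataclass(frozen=True)
class FitResult:
    model_id: str
    coeffs: tuple[float, ...]
    r_squared: float
    residual_norm: float  # MPa, sqrt of SS_res
    converged: bool
    n_points: int

    @property
    def params(self) -> HyperelasticParams:
        return HyperelasticParams(self.model_id, self.coeffs)

    def to_dict(self) -> dict:
        return {
            "model": self.model_id,
            "coeffs": list(self.coeffs),
            "r_squared": self.r_squared,
            "residual_norm": self.residual_norm,
            "converged": self.converged,
            "n_points": self.n_points,
        }


@dataclass(frozen=True)
class ModelRanking:
    results: tuple[FitResult, ...]  # descending R^2, ties -> fewer params

    @property
    def best_model(self) -> str:
        return self.results[0].model_id

    def __iter__(self):
        return iter(self.results)


def r_squared(observed, predicted) -> float:
    """R^2 = 1 - SS_res / SS_tot, with SS_tot about the observed mean."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 3:
        raise ValueError("need equal-length series with at least 3 points")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined for constant observations")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def _heuristic_start(model_id: str, e0: float) -> np.ndarray:
    """Deterministic start matching the curve's small-strain modulus e0.

    Uses the Neo-Hookean equivalence a1 = E0/6 as the stress scale; unit
    exponents/second terms elsewhere.
    """
    s = max(abs(e0) / 6.0, 1e-3)
    starts = {
        "neo_hookean": [s],
        "mooney_rivlin": [s, 0.0],
        "yeoh": [s, 0.0, 0.0],
        "fung": [2.0 * s, 1.0],
        "humphrey": [s, 1.0],
        "veronda_westmann": [2.0 * s, 1.0],
        "ogden": [s, 2.0, s / 10.0, 4.0, s / 10.0, -2.0],
    }
    return np.array(starts[model_id], dtype=float)


def _random_start(model_id: str, e0: float, rng: np.random.Generator) -> np.ndarray:
    scale = max(abs(e0) / 6.0, 1e-3)
    n = MODELS[model_id]
    exps = _EXPONENT_SLOTS.get(model_id, ())
    x0 = np.empty(n)
    for i in range(n):
        if i in exps:
            x0[i] = rng.uniform(0.1, 20.0) * rng.choice([1.0, -1.0]) if (
                model_id == "ogden"
            ) else rng.uniform(0.1, 20.0)
        else:
            mag = scale * 10.0 ** rng.uniform(-1.0, 1.0)
            x0[i] = mag * rng.choice([1.0, -1.0])
    return x0


def fit_model(
    curve: StressStretchCurve,
    model_id: str,
    init: np.ndarray | None = None,
    n_starts: int = _N_STARTS_DEFAULT,
    seed: int = 0,
) -> FitResult:
    """Fit one model to a curve by multistart Levenberg-Marquardt.

    The best local optimum over ``n_starts`` initializations is returned;
    with a fixed seed the result is reproducible.
    """
    if model_id not in MODELS:
        raise ValueError(f"unknown model {model_id!r}")
    lam = curve.stretch
    obs = curve.stress
    n_min = max(MODELS[model_id] + 2, 10)
    if lam.size < n_min:
        raise ValueError(f"{model_id} needs >= {n_min} grid points, got {lam.size}")

    def residuals(c):
        return _predict(model_id, c, lam) - obs

    try:
        e0, _ = linear_modulus(curve, lambda_max=curve.lambda_max, _validate=False)
    except ValueError:  # flat curve: fall back to a unit stress scale
        e0 = 6.0
    rng = np.random.default_rng(seed)
    starts = [init] if init is not None else [_heuristic_start(model_id, e0)]
    while len(starts) < n_starts:
        starts.append(_random_start(model_id, e0, rng))

    best = None
    any_converged = False
    for x0 in starts:
        try:
            sol = least_squares(residuals, np.asarray(x0, float), method="lm",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=300)
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        if best is None or sol.cost < best.cost - 1e-18:
            best = sol
        any_converged = any_converged or (sol.status > 0)
    if best is None:
        return FitResult(model_id, tuple(np.full(MODELS[model_id], np.nan)),
                         float("-inf"), float("inf"), False, int(lam.size))
    coeffs = tuple(float(v) for v in best.x)
    pred = _predict(model_id, best.x, lam)
    return FitResult(
        model_id=model_id,
        coeffs=coeffs,
        r_squared=r_squared(obs, pred),
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        converged=bool(any_converged and best.status > 0),
        n_points=int(lam.size),
    )


def _predict(model_id: str, c: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Model stress without the HyperelasticParams validity gate (the
    optimizer may wander through a2 = 0)."""
    c = np.asarray(c, dtype=float)
    if model_id in _EXPONENT_SLOTS and model_id != "ogden" and c[1] == 0.0:
        c = c.copy()
        c[1] = 1e-12
    if model_id == "ogden":
        c = c.copy()
        for slot in (1, 3, 5):
            if c[slot] == 0.0:
                c[slot] = 1e-12
    return np.asarray(cauchy_stress(HyperelasticParams(model_id, tuple(c)), lam))


def fit_all_models(
    curve: StressStretchCurve,
    n_starts: int = _N_STARTS_DEFAULT,
    seed: int = 0,
) -> ModelRanking:
    """Fit all seven models and rank by descending R^2 (at 0.001
    resolution; ties go to the model with fewer coefficients)."""
    results = [
        fit_model(curve, m, n_starts=n_starts, seed=seed) for m in MODELS
    ]
    results.sort(
        key=lambda r: (-round(r.r_squared / R2_TIE_RESOLUTION), MODELS[r.model_id])
    )
    return ModelRanking(tuple(results))


def linear_modulus(
    curve: StressStretchCurve,
    lambda_max: float = 1.2,
    _validate: bool = True,
) -> tuple[float, float]:
    """Quasi-linear Young's modulus: OLS slope of sigma on (lambda - 1).

    Fits with a free intercept over stretches up to ``lambda_max``; returns
    (modulus in MPa, R^2 of the linear fit).
    """
    mask = curve.stretch <= lambda_max + 1e-9
    lam = curve.stretch[mask]
    sig = curve.stress[mask]
    if _validate and curve.lambda_max < lambda_max - 1e-9:
        raise ValueError(
            f"curve reaches only lambda={curve.lambda_max}, need {lambda_max}"
        )
    if lam.size < 3:
        raise ValueError("need at least 3 points for the linear fit")
    strain = lam - 1.0
    slope, intercept = np.polyfit(strain, sig, 1)
    pred = slope * strain + intercept
    return float(slope), r_squared(sig, pred)
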