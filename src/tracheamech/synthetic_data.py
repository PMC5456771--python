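"""Synthetic tensile-test cohorts with the statistical structure of a
human tracheal study.

The generator emits per-specimen force-displacement CSVs (plus a manifest
and a ground-truth sidecar) for a cohort of 30 subjects — 13 young
(5 female / 8 male, ages 18-36) and 17 old (7 female / 10 male, ages
49-65) — with three specimens of each tissue per subject.  Each tissue's
mean behavior is a Yeoh material (coefficients from the published fits);
subject-to-subject stiffness heterogeneity is a lognormal multiplicative
scale, moment-matched for cartilage so the young/old group moduli
reproduce 13.30 +/- 5.72 and 20.71 +/- 10.17 MPa.  Forces are the inverse
of the processing equations (T = sigma A0 / lambda) plus the 0.1 N preload
and additive Gaussian noise, so every pipeline stage is exercised.
"""

from __future__ import annotations

import functools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .constitutive import HyperelasticParams, cauchy_stress
from .fitting import linear_modulus
from .tensile_processing import (
    DEFAULT_LAMBDA_MAX,
    DEFAULT_PRELOAD_N,
    GRID_STEP,
    ForceDisplacementRecord,
    SpecimenGeometry,
    StressStretchCurve,
    uniform_grid,
    write_record_csv,
)

__all__ = [
    "CohortConfig",
    "Cohort",
    "sample_subject_scale",
    "simulate_record",
    "generate_cohort",
]

#: published Yeoh fits used as per-tissue ground-truth mean behavior (MPa)
DEFAULT_TISSUE_PARAMS = {
    "cartilage": HyperelasticParams("yeoh", (3.583, -2.534, 12.020)),
    "smooth_muscle": HyperelasticParams("yeoh", (0.063, 0.394, -0.171)),
    "connective": HyperelasticParams("yeoh", (0.257, 0.483, -0.148)),
}

#: measured gauge-length distributions, mm (mean, sd)
DEFAULT_L0 = {
    "cartilage": (4.13, 1.81),
    "smooth_muscle": (6.37, 1.91),
    "connective": (1.60, 0.33),
}

#: cross-section distributions, mm^2 (mean, sd) — fixture choice, the
#: study prints none; A0 scales forces but cancels out of stresses
DEFAULT_A0 = {
    "cartilage": (5.0, 1.5),
    "smooth_muscle": (3.0, 1.0),
    "connective": (3.0, 1.0),
}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort; ``seed`` is mandatory."""

    seed: int
    n_young_f: int = 5
    n_young_m: int = 8
    n_old_f: int = 7
    n_old_m: int = 10
    specimens_per_tissue: int = 3
    tissues: tuple[str, ...] = tuple(DEFAULT_TISSUE_PARAMS)
    tissue_params: dict = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_PARAMS)
    )
    # cartilage group modulus targets, MPa (mean, sd)
    cartilage_young: tuple[float, float] = (13.30, 5.72)
    cartilage_old: tuple[float, float] = (20.71, 10.17)
    # soft-tissue stiffness scales: old/young mean ratio and CoV of the
    # subject scale; smooth muscle is the least age-sensitive tissue
    soft_old_ratio: dict = field(
        default_factory=lambda: {"smooth_muscle": 1.10, "connective": 1.30}
    )
    soft_scale_cov: float = 0.30
    L0_dist: dict = field(default_factory=lambda: dict(DEFAULT_L0))
    A0_dist: dict = field(default_factory=lambda: dict(DEFAULT_A0))
    lambda_max: dict = field(default_factory=lambda: dict(DEFAULT_LAMBDA_MAX))
    noise_rel: float = 0.01  # force noise SD relative to peak force
    preload_N: float = DEFAULT_PRELOAD_N
    grid_step: float = GRID_STEP

    def __post_init__(self) -> None:
        for n in (self.n_young_f, self.n_young_m, self.n_old_f, self.n_old_m):
            if n < 0:
                raise ValueError("subject counts must be >= 0")
        if self.noise_rel < 0 or self.soft_scale_cov < 0:
            raise ValueError("dispersions must be >= 0")

    @property
    def n_subjects(self) -> int:
        return self.n_young_f + self.n_young_m + self.n_old_f + self.n_old_m


@dataclass(frozen=True)
class Cohort:
    records: tuple[ForceDisplacementRecord, ...]
    manifest: pd.DataFrame  # one row per specimen, with subject metadata
    subjects: pd.DataFrame  # one row per subject: subject_id, age, age_group, sex
    ground_truth: dict


@functools.lru_cache(maxsize=32)
def _base_modulus(params: HyperelasticParams, lambda_max: float = 1.2) -> float:
    """Linear modulus of the noiseless ground-truth curve over [1, lambda_max]."""
    grid = uniform_grid(lambda_max)
    curve = StressStretchCurve(
        stretch=grid, stress=np.asarray(cauchy_stress(params, grid)),
        tissue="cartilage",
    )
    e, _ = linear_modulus(curve, lambda_max=lambda_max)
    return e


def _lognormal_draw(mean: float, sd: float, rng: np.random.Generator) -> float:
    """One draw from the lognormal with the given arithmetic mean and SD."""
    if mean <= 0:
        raise ValueError("lognormal moment matching needs mean > 0")
    if sd == 0:
        return mean
    s2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - s2 / 2.0
    return float(np.exp(rng.normal(mu, math.sqrt(s2))))


def sample_subject_scale(
    config: CohortConfig,
    age_group: str,
    rng: np.random.Generator,
    tissue: str = "cartilage",
) -> float:
    """Positive stiffness multiplier for one subject-tissue.

    For cartilage the multiplier is calibrated so scale * E_base matches
    the group's target modulus mean and SD (E_base being the linear
    modulus of the tissue's ground-truth curve over [1, 1.2]); soft
    tissues use a unit young mean, a configured old/young ratio and CoV.
    """
    if tissue == "cartilage":
        mean, sd = (
            config.cartilage_young if age_group == "young" else config.cartilage_old
        )
        e_base = _base_modulus(config.tissue_params["cartilage"])
        return _lognormal_draw(mean / e_base, sd / e_base, rng)
    ratio = 1.0 if age_group == "young" else config.soft_old_ratio[tissue]
    return _lognormal_draw(ratio, config.soft_scale_cov * ratio, rng)


def _positive_normal(mean: float, sd: float, rng: np.random.Generator) -> float:
    """Normal draw, redrawn while below 20% of the mean (geometry cannot
    be vanishingly small or negative)."""
    lo = 0.2 * mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > lo:
            return float(x)
    raise RuntimeError("geometry sampling failed")  # pragma: no cover


def simulate_record(
    params: HyperelasticParams,
    scale: float,
    geometry: SpecimenGeometry,
    lambda_max: float,
    noise_sd: float,
    rng: np.random.Generator,
    specimen_id: str = "sim",
    subject_id: str = "sim",
    tissue: str = "cartilage",
    preload: float = DEFAULT_PRELOAD_N,
    step: float = GRID_STEP,
) -> ForceDisplacementRecord:
    """Invert the processing equations to produce one noisy record.

    On the stretch grid [1, lambda_max]: force = scale*sigma(lambda)*A0 /
    lambda + preload + Gaussian noise with SD = noise_sd * peak force;
    displacement = (lambda - 1) * L0.  A short sub-preload toe (linear ramp
    from specimen contact up to the 0.1 N crossing, machine-zeroed and kept
    noise-free below the measurement range) precedes the grid so that the
    preload re-referencing step is exercised on every record.
    """
    if lambda_max <= 1:
        raise ValueError("lambda_max must exceed 1")
    grid = uniform_grid(lambda_max, step)
    sig = scale * np.asarray(cauchy_stress(params, grid))
    force = sig * geometry.A0 / grid + preload
    if noise_sd > 0:
        force = force + rng.normal(0.0, noise_sd * float(np.max(np.abs(force))),
                                   size=force.shape)
        # the preloaded reference state itself is recorded exactly
        force[0] = preload
    # toe: approximate small-strain stiffness maps the preload to a
    # contact-to-crossing displacement; 4 samples strictly below preload
    tangent = (force[1] - force[0]) / (geometry.L0 * step)
    dl_pre = preload / tangent if tangent > 0 else 0.05 * geometry.L0
    frac = np.array([0.0, 0.25, 0.5, 0.75])
    toe_disp = frac * dl_pre
    toe_force = frac * preload
    return ForceDisplacementRecord(
        specimen_id=specimen_id,
        subject_id=subject_id,
        tissue=tissue,
        displacement=np.concatenate([toe_disp, dl_pre + (grid - 1.0) * geometry.L0]),
        force=np.concatenate([toe_force, force]),
        geometry=geometry,
    )


def _iter_subjects(config: CohortConfig) -> Iterator[tuple[str, str, str]]:
    groups = [
        ("young", "female", config.n_young_f),
        ("young", "male", config.n_young_m),
        ("old", "female", config.n_old_f),
        ("old", "male", config.n_old_m),
    ]
    i = 0
    for age_group, sex, n in groups:
        for _ in range(n):
            i += 1
            yield f"S{i:02d}", age_group, sex


_AGE_RANGES = {"young": (18.0, 36.0), "old": (49.0, 65.0)}


def generate_cohort(config: CohortConfig, out_dir: str | Path | None = None) -> Cohort:
    """Generate a full cohort; optionally write the CSV/JSON artifacts.

    Writes ``records/<specimen_id>.csv``, ``manifest.csv``,
    ``subjects.csv`` and ``ground_truth.json`` under ``out_dir`` when
    given.  Fully deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    records: list[ForceDisplacementRecord] = []
    manifest_rows: list[dict] = []
    subject_rows: list[dict] = []
    truth_scales: dict[str, dict[str, float]] = {}

    for subject_id, age_group, sex in _iter_subjects(config):
        lo, hi = _AGE_RANGES[age_group]
        age = float(np.round(rng.uniform(lo, hi), 1))
        subject_rows.append(
            {"subject_id": subject_id, "age": age, "age_group": age_group,
             "sex": sex}
        )
        truth_scales[subject_id] = {}
        for tissue in config.tissues:
            scale = sample_subject_scale(config, age_group, rng, tissue)
            truth_scales[subject_id][tissue] = scale
            params = config.tissue_params[tissue]
            for k in range(config.specimens_per_tissue):
                specimen_id = f"{subject_id}_{tissue}_{k + 1}"
                geometry = SpecimenGeometry(
                    L0=_positive_normal(*config.L0_dist[tissue], rng),
                    A0=_positive_normal(*config.A0_dist[tissue], rng),
                )
                rec = simulate_record(
                    params,
                    scale,
                    geometry,
                    lambda_max=config.lambda_max[tissue],
                    noise_sd=config.noise_rel,
                    rng=rng,
                    specimen_id=specimen_id,
                    subject_id=subject_id,
                    tissue=tissue,
                    preload=config.preload_N,
                    step=config.grid_step,
                )
                records.append(rec)
                manifest_rows.append(
                    {
                        "specimen_id": specimen_id,
                        "subject_id": subject_id,
                        "tissue": tissue,
                        "L0_mm": geometry.L0,
                        "A0_mm2": geometry.A0,
                        "age": age,
                        "age_group": age_group,
                        "sex": sex,
                    }
                )

    manifest_cols = ["specimen_id", "subject_id", "tissue", "L0_mm", "A0_mm2",
                     "age", "age_group", "sex"]
    subject_cols = ["subject_id", "age", "age_group", "sex"]
    manifest = pd.DataFrame(manifest_rows, columns=manifest_cols)
    subjects = pd.DataFrame(subject_rows, columns=subject_cols)
    ground_truth = {
        "seed": config.seed,
        "tissue_params": {
            t: {"model": p.model_id, "coeffs": list(p.coeffs)}
            for t, p in config.tissue_params.items()
        },
        "base_modulus_MPa": {
            "cartilage": _base_modulus(config.tissue_params["cartilage"])
            if "cartilage" in config.tissue_params
            else None
        },
        "subject_scales": truth_scales,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        rec_dir = out_dir / "records"
        rec_dir.mkdir(parents=True, exist_ok=True)
        for rec in records:
            write_record_csv(rec, rec_dir / f"{rec.specimen_id}.csv")
        manifest.to_csv(out_dir / "manifest.csv", index=False,
                        float_format="%.9g")
        subjects.to_csv(out_dir / "subjects.csv", index=False,
                        float_format="%.9g")
        (out_dir / "ground_truth.json").write_text(
            json.dumps(ground_truth, indent=2, sort_keys=True)
        )

    return Cohort(
        records=tuple(records),
        manifest=manifest,
        subjects=subjects,
        ground_truth=ground_truth,
    )
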