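"""Raw uniaxial force-displacement records -> Cauchy stress-stretch curves.

Incompressibility gives lambda = (L0 + dL)/L0 and sigma = (T/A0) * lambda
with T in N, A0 in mm^2, so sigma comes out in MPa.  The reference state is
the first crossing of a small tensile preload (default 0.1 N, at which the
gauge length L0 is measured); the reference force is subtracted before the
stress conversion so that sigma(1) = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TISSUES = ("cartilage", "smooth_muscle", "connective")

#: maximum stretch to which curves are averaged / fitted, per tissue
DEFAULT_LAMBDA_MAX = {"cartilage": 1.2, "smooth_muscle": 1.5, "connective": 1.5}

DEFAULT_PRELOAD_N = 0.1
GRID_STEP = 0.01


@dataclass(frozen=True)
class SpecimenGeometry:
    """Initial gauge length L0 (mm) and cross-section A0 (mm^2)."""

    L0: float
    A0: float

    def __post_init__(self) -> None:
        if self.L0 <= 0:
            raise ValueError("L0 must be positive")
        if self.A0 <= 0:
            raise ValueError("A0 must be positive")


@dataclass(frozen=True)
class ForceDisplacementRecord:
    specimen_id: str
    subject_id: str
    tissue: str
    displacement: np.ndarray  # mm, monotone non-decreasing
    force: np.ndarray  # N
    geometry: SpecimenGeometry

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        d = np.asarray(self.displacement, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if d.shape != f.shape or d.ndim != 1 or d.size < 2:
            raise ValueError("displacement and force must be equal-length 1-D, n >= 2")
        object.__setattr__(self, "displacement", d)
        object.__setattr__(self, "force", f)


@dataclass(frozen=True)
class StressStretchCurve:
    stretch: np.ndarray  # dimensionless, strictly increasing from 1.0
    stress: np.ndarray  # MPa
    tissue: str
    n_samples: int = 1
    stress_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        lam = np.asarray(self.stretch, dtype=float)
        sig = np.asarray(self.stress, dtype=float)
        if lam.shape != sig.shape or lam.ndim != 1 or lam.size < 2:
            raise ValueError("stretch and stress must be equal-length 1-D, n >= 2")
        if abs(lam[0] - 1.0) > 1e-9:
            raise ValueError("stretch series must start at 1.0")
        if np.any(np.diff(lam) <= 0):
            raise ValueError("stretch series must be strictly increasing")
        object.__setattr__(self, "stretch", lam)
        object.__setattr__(self, "stress", sig)
        if self.stress_sd is not None:
            sd = np.asarray(self.stress_sd, dtype=float)
            if sd.shape != lam.shape:
                raise ValueError("stress_sd shape mismatch")
            object.__setattr__(self, "stress_sd", sd)

    @property
    def lambda_max(self) -> float:
        return float(self.stretch[-1])


def stretch_from_displacement(delta_L, L0: float):
    """lambda = (L0 + dL) / L0 for dL >= 0 (mm)."""
    if L0 <= 0:
        raise ValueError("L0 must be positive")
    dL = np.asarray(delta_L, dtype=float)
    if np.any(dL < 0):
        raise ValueError("negative displacement (compression) not modeled")
    out = (L0 + dL) / L0
    return float(out) if np.ndim(delta_L) == 0 else out


def cauchy_stress_from_force(T, A0: float, lambda_):
    """sigma = (T / A0) * lambda, MPa for T in N and A0 in mm^2."""
    if A0 <= 0:
        raise ValueError("A0 must be positive")
    sig = np.asarray(T, dtype=float) / A0 * np.asarray(lambda_, dtype=float)
    return float(sig) if np.ndim(T) == 0 and np.ndim(lambda_) == 0 else sig


def preload_reference(
    record: ForceDisplacementRecord, preload: float = DEFAULT_PRELOAD_N
) -> ForceDisplacementRecord:
    """Re-origin a record at the first sample where force >= preload.

    Samples before the crossing are discarded and the crossing displacement
    becomes zero, mirroring measurement of L0 at the preloaded state.
    """
    idx = np.flatnonzero(record.force >= preload)
    if idx.size == 0:
        raise ValueError(
            f"specimen {record.specimen_id}: force never reaches the "
            f"{preload} N preload (max {record.force.max():.4g} N)"
        )
    i0 = int(idx[0])
    return replace(
        record,
        displacement=record.displacement[i0:] - record.displacement[i0],
        force=record.force[i0:],
    )


def _enforce_monotone(record: ForceDisplacementRecord) -> ForceDisplacementRecord:
    """Drop samples whose displacement does not strictly increase (jitter)."""
    d = record.displacement
    keep = np.r_[True, d[1:] > np.maximum.accumulate(d)[:-1]]
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning(
            "specimen %s: dropped %d non-increasing displacement samples",
            record.specimen_id, n_drop,
        )
        record = replace(
            record, displacement=d[keep], force=record.force[keep]
        )
    return record


def record_to_curve(
    record: ForceDisplacementRecord, preload: float = DEFAULT_PRELOAD_N
) -> StressStretchCurve:
    """Convert a force-displacement record to a Cauchy stress-stretch curve.

    Applies the preload re-origin, subtracts the reference force (the
    preload, carried by the specimen at lambda = 1) and maps the remaining
    force through sigma = (T/A0) lambda.
    """
    rec = preload_reference(record, preload)
    rec = _enforce_monotone(rec)
    lam = stretch_from_displacement(rec.displacement, rec.geometry.L0)
    net_force = rec.force - rec.force[0]
    sig = cauchy_stress_from_force(net_force, rec.geometry.A0, lam)
    return StressStretchCurve(stretch=lam, stress=sig, tissue=rec.tissue)


def resample_to_grid(
    curve: StressStretchCurve, grid: Sequence[float]
) -> StressStretchCurve:
    """Linearly interpolate the stress onto a new stretch grid (no
    extrapolation)."""
    g = np.asarray(grid, dtype=float)
    # endpoint slack of 1e-6 in stretch absorbs the finite precision of
    # CSV round trips; anything larger is real extrapolation
    tol = 1e-6
    if g[0] < curve.stretch[0] - tol or g[-1] > curve.stretch[-1] + tol:
        raise ValueError(
            f"grid [{g[0]}, {g[-1]}] outside curve range "
            f"[{curve.stretch[0]}, {curve.stretch[-1]}]"
        )
    g_eval = np.clip(g, curve.stretch[0], curve.stretch[-1])
    sig = np.interp(g_eval, curve.stretch, curve.stress)
    return StressStretchCurve(
        stretch=g, stress=sig, tissue=curve.tissue, n_samples=curve.n_samples
    )


def uniform_grid(lambda_max: float, step: float = GRID_STEP) -> np.ndarray:
    """Stretch grid [1, lambda_max] with fixed step (endpoint included)."""
    n = int(round((lambda_max - 1.0) / step))
    return 1.0 + step * np.arange(n + 1)


def average_curves(
    curves: Iterable[StressStretchCurve],
    lambda_max: float | None = None,
    step: float = GRID_STEP,
) -> StressStretchCurve:
    """Pointwise mean +/- sample SD of curves on a uniform stretch grid.

    Curves not reaching lambda_max are excluded (with a warning) so that
    every grid point averages the same specimens; default lambda_max is the
    tissue convention (1.2 cartilage, 1.5 soft tissues).
    """
    curves = list(curves)
    if not curves:
        raise ValueError("need at least one curve")
    tissues = {c.tissue for c in curves}
    if len(tissues) != 1:
        raise ValueError(f"curves mix tissues: {sorted(tissues)}")
    tissue = curves[0].tissue
    if lambda_max is None:
        lambda_max = DEFAULT_LAMBDA_MAX[tissue]
    grid = uniform_grid(lambda_max, step)
    usable = []
    for c in curves:
        if c.lambda_max < lambda_max - 1e-6:
            logger.warning(
                "%s curve reaching only lambda=%.3f excluded from average to %.3f",
                tissue, c.lambda_max, lambda_max,
            )
            continue
        usable.append(resample_to_grid(c, grid).stress)
    if not usable:
        raise ValueError(f"no {tissue} curve reaches lambda_max={lambda_max}")
    stack = np.vstack(usable)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(usable) > 1 else np.zeros_like(mean)
    return StressStretchCurve(
        stretch=grid,
        stress=mean,
        tissue=tissue,
        n_samples=len(usable),
        stress_sd=sd,
    )


# ---------------------------------------------------------------------------
# CSV interchange


def write_record_csv(record: ForceDisplacementRecord, path: str | Path) -> None:
    pd.DataFrame(
        {"displacement_mm": record.displacement, "force_N": record.force}
    ).to_csv(path, index=False, float_format="%.9g")


def read_record_csv(
    path: str | Path,
    specimen_id: str,
    subject_id: str,
    tissue: str,
    geometry: SpecimenGeometry,
) -> ForceDisplacementRecord:
    df = pd.read_csv(path)
    return ForceDisplacementRecord(
        specimen_id=specimen_id,
        subject_id=subject_id,
        tissue=tissue,
        displacement=df["displacement_mm"].to_numpy(),
        force=df["force_N"].to_numpy(),
        geometry=geometry,
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Specimen manifest: specimen_id, subject_id, tissue, L0_mm, A0_mm2
    (plus any subject metadata columns such as age, sex)."""
    df = pd.read_csv(path)
    required = {"specimen_id", "subject_id", "tissue", "L0_mm", "A0_mm2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def load_records(manifest: pd.DataFrame, data_dir: str | Path):
    """Yield ForceDisplacementRecords for every manifest row; record CSVs
    are looked up as <data_dir>/<specimen_id>.csv."""
    data_dir = Path(data_dir)
    for row in manifest.itertuples(index=False):
        yield read_record_csv(
            data_dir / f"{row.specimen_id}.csv",
            specimen_id=row.specimen_id,
            subject_id=row.subject_id,
            tissue=row.tissue,
            geometry=SpecimenGeometry(L0=row.L0_mm, A0=row.A0_mm2),
        )


def write_curve_csv(curve: StressStretchCurve, path: str | Path) -> None:
    df = pd.DataFrame({"stretch": curve.stretch, "stress_MPa": curve.stress})
    if curve.stress_sd is not None:
        df["stress_sd_MPa"] = curve.stress_sd
    df.to_csv(path, index=False, float_format="%.9g")
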