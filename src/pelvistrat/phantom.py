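"""Synthetic pelvis-mask cohorts with a known geometry-to-difficulty mechanism.

Real pelvic MRI cannot be redistributed, so the pipeline is exercised on
stylised binary bone phantoms: two lateral "iliac wing" shells whose minimal
left-right separation defines a pelvic *inlet width*, plus a posterior midline
"sacrococcyx" wall.  Surgical difficulty labels are drawn from a logistic
model of inlet narrowness and clinical covariates (sex, BMI, neoadjuvant
therapy), with effect directions matching the clinical observation that
difficult pelves are narrower and difficult patients are more often male,
heavier, and more often irradiated.

Array axes are ordered (left-right, anterior-posterior, inferior-superior);
all physical quantities are in millimetres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import MeasurementError, SizingError

__all__ = [
    "PhantomSpec",
    "ClinicalCovariates",
    "LogisticCoefficients",
    "LabeledCase",
    "CohortConfig",
    "Cohort",
    "generate_pelvis_phantom",
    "measure_inlet_width",
    "inlet_band_mask",
    "latent_difficulty",
    "generate_cohort",
    "save_cohort",
]

# Fixed geometry fractions of the grid's physical extents (see docs/methods.md):
_WING_Z = (0.10, 0.90)      # inferior-superior extent of all bone
_WING_Y = (0.15, 0.60)      # anterior-posterior band occupied by the wings
_SACRUM_Y0 = 0.68           # anterior face of the posterior midline wall
_FLARE_FRAC = 0.06          # outward flare of the wings away from the narrowest level


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of one pelvis phantom on an isotropic voxel grid."""

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_spacing_mm: float = 1.5
    ilium_thickness_mm: float = 3.0
    sacrum_depth_mm: float = 10.0
    inlet_width_mm: float = 20.0
    jitter_mm: float = 0.8

    def physical_extent(self) -> tuple[float, float, float]:
        return tuple(n * self.voxel_spacing_mm for n in self.grid_shape)

    def validate(self) -> None:
        if self.voxel_spacing_mm <= 0:
            raise SizingError("voxel spacing must be positive")
        if min(self.grid_shape) < 8:
            raise SizingError("grid too small to hold a pelvis phantom")
        if self.ilium_thickness_mm < 0 or self.sacrum_depth_mm <= 0 or self.inlet_width_mm <= 0:
            raise SizingError("physical dimensions must be positive")
        ex, ey, _ = self.physical_extent()
        if self.inlet_width_mm >= ex:
            raise SizingError("inlet width exceeds the grid's physical width")
        half_needed = self.inlet_width_mm / 2 + _FLARE_FRAC * ex + self.ilium_thickness_mm + self.jitter_mm
        if half_needed > ex / 2 - self.voxel_spacing_mm:
            raise SizingError("wings do not fit laterally on the grid")
        if _SACRUM_Y0 * ey + self.ilium_thickness_mm > 0.95 * ey:
            raise SizingError("posterior wall does not fit in the grid depth")


@dataclass(frozen=True)
class ClinicalCovariates:
    """Per-patient clinical variables used alongside the image."""

    bmi: float
    male: int
    neoadjuvant: int

    def __post_init__(self) -> None:
        if not (10.0 <= self.bmi <= 60.0):
            raise ValueError("BMI outside the plausible range [10, 60] kg/m^2")
        if self.male not in (0, 1) or self.neoadjuvant not in (0, 1):
            raise ValueError("binary flags must be 0 or 1")


@dataclass(frozen=True)
class LogisticCoefficients:
    """Logistic model of difficulty: intercept + slopes on standardized predictors.

    ``narrowness`` multiplies the standardized *narrowness* score (negative
    standardized inlet width), ``bmi`` multiplies the BMI z-score; positive
    slopes make narrow, male, heavy and irradiated pelves more difficult.
    """

    intercept: float = 0.0
    narrowness: float = 4.0
    male: float = 2.0
    bmi: float = 0.6
    neoadjuvant: float = 1.2


@dataclass
class LabeledCase:
    """One subject: binary pelvis volume, spacing, covariates, difficulty label."""

    case_id: str
    volume: np.ndarray
    spacing_mm: tuple[float, float, float]
    covariates: ClinicalCovariates
    label: int
    latent_p: float
    inlet_width_mm: float | None = None


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings for a synthetic cohort.

    Covariate defaults mirror the clinical cohort this pipeline targets:
    ~68% male, ~71% neoadjuvant-treated, BMI ~ Normal(24.1, 3.4) kg/m^2, and
    an overall difficult fraction near 0.491.  Inlet widths are Normal
    (clipped at 2.5 SD) so narrowness has a well-defined z-score.
    """

    n_cases: int = 108
    coefficients: LogisticCoefficients = field(default_factory=LogisticCoefficients)
    male_rate: float = 0.68
    neoadjuvant_rate: float = 0.71
    bmi_mean: float = 24.1
    bmi_sd: float = 3.4
    inlet_mean_mm: float = 20.0
    inlet_sd_mm: float = 3.0
    target_prevalence: Optional[float] = 53 / 108
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 8:
            raise ValueError("a cohort needs at least 8 cases")
        if self.target_prevalence is not None and not (0 < self.target_prevalence < 1):
            raise ValueError("target prevalence must lie strictly in (0, 1)")


@dataclass
class Cohort:
    cases: list[LabeledCase]
    manifest: pd.DataFrame
    meta: dict


def _smooth_field(rng: np.random.Generator, shape: tuple[int, ...], amplitude: float) -> np.ndarray:
    """Spatially smooth zero-mean noise with standard deviation ~= amplitude."""
    if amplitude <= 0:
        return np.zeros(shape)
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=2.0, mode="nearest")
    sd = smooth.std()
    return smooth * (amplitude / sd) if sd > 0 else smooth


def generate_pelvis_phantom(spec: PhantomSpec, seed: int) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Rasterize one binary pelvis phantom; deterministic given (spec, seed).

    Returns the uint8 volume and its isotropic spacing.  With small jitter the
    volume contains exactly three connected components (left wing, right wing,
    posterior wall); a zero shell thickness rasterizes no bone at all.
    """
    spec.validate()
    nx, ny, nz = spec.grid_shape
    s = spec.voxel_spacing_mm
    ex, ey, ez = spec.physical_extent()
    rng = np.random.default_rng(seed)

    xc = (np.arange(nx) + 0.5) * s - ex / 2          # centered left-right coordinate
    yc = (np.arange(ny) + 0.5) * s                   # anterior -> posterior
    zc = (np.arange(nz) + 0.5) * s

    z0, z1 = _WING_Z[0] * ez, _WING_Z[1] * ez
    y0, y1 = _WING_Y[0] * ey, _WING_Y[1] * ey
    z_mid = (z0 + z1) / 2
    flare = _FLARE_FRAC * ex

    # Inner half-gap of the wings per axial level: narrowest at mid-height.
    rel = (zc - z_mid) / (0.5 * (z1 - z0))
    half_gap = spec.inlet_width_mm / 2 + flare * rel**2

    in_band = (yc[:, None] >= y0) & (yc[:, None] <= y1) & (zc[None, :] >= z0) & (zc[None, :] <= z1)
    jit_l = _smooth_field(rng, (ny, nz), spec.jitter_mm)
    jit_r = _smooth_field(rng, (ny, nz), spec.jitter_mm)
    hg_l = np.where(in_band, half_gap[None, :] + jit_l, np.inf)
    hg_r = np.where(in_band, half_gap[None, :] + jit_r, np.inf)

    t = spec.ilium_thickness_mm
    x3 = xc[:, None, None]
    left = (-x3 >= hg_l[None]) & (-x3 < hg_l[None] + t)
    right = (x3 >= hg_r[None]) & (x3 < hg_r[None] + t)

    # Posterior midline wall ("sacrococcyx"): same shell thickness as the wings.
    jit_s = _smooth_field(rng, (nx, nz), spec.jitter_mm)
    y_sac = _SACRUM_Y0 * ey + jit_s
    y3 = yc[None, :, None]
    sacrum = (
        (y3 >= y_sac[:, None, :])
        & (y3 < y_sac[:, None, :] + t)
        & (np.abs(x3) <= spec.sacrum_depth_mm / 2)
        & (zc[None, None, :] >= z0)
        & (zc[None, None, :] <= z1)
    )

    volume = (left | right | sacrum).astype(np.uint8)
    return volume, (s, s, s)


def _lateral_components(volume: np.ndarray):
    labels, n = ndimage.label(volume)
    if n == 0:
        raise MeasurementError("empty volume: no lateral components")
    centroids = ndimage.center_of_mass(volume, labels, index=range(1, n + 1))
    xs = [c[0] for c in centroids]
    left_lab = int(np.argmin(xs)) + 1
    right_lab = int(np.argmax(xs)) + 1
    return labels, left_lab, right_lab


def measure_inlet_width(volume: np.ndarray, spacing_mm) -> float:
    """Minimal left-right physical gap between the two lateral bone components.

    Scans every (anterior-posterior, inferior-superior) row that intersects
    both lateral components and returns the smallest empty-voxel gap times the
    left-right spacing.  A single component bridging the midline yields 0 mm;
    fewer than two lateral structures raise :class:`MeasurementError`.
    """
    sx = float(np.atleast_1d(spacing_mm)[0])
    labels, left_lab, right_lab = _lateral_components(volume)
    nx = volume.shape[0]
    if left_lab == right_lab:
        idx = np.nonzero(labels == left_lab)[0]
        if idx.min() < nx / 3 and idx.max() >= 2 * nx / 3:
            return 0.0  # one solid structure spanning the midline: touching slabs
        raise MeasurementError("fewer than two lateral components")
    lmask = labels == left_lab
    rmask = labels == right_lab
    rows = lmask.any(axis=0) & rmask.any(axis=0)
    if not rows.any():
        raise MeasurementError("lateral components share no axial row")
    x = np.arange(nx)
    lmax = np.max(np.where(lmask, x[:, None, None], -1), axis=0)
    rmin = np.min(np.where(rmask, x[:, None, None], nx), axis=0)
    gaps = rmin - lmax - 1
    return float(max(gaps[rows].min(), 0) * sx)


def inlet_band_mask(volume: np.ndarray, dilate: int = 2) -> np.ndarray:
    """Boolean mask of the region between the wing shells, dilated by ``dilate`` voxels."""
    labels, left_lab, right_lab = _lateral_components(volume)
    if left_lab == right_lab:
        raise MeasurementError("fewer than two lateral components")
    nx = volume.shape[0]
    x = np.arange(nx)
    lmask = labels == left_lab
    rmask = labels == right_lab
    rows = lmask.any(axis=0) & rmask.any(axis=0)
    lmax = np.max(np.where(lmask, x[:, None, None], -1), axis=0)
    rmin = np.min(np.where(rmask, x[:, None, None], nx), axis=0)
    band = (x[:, None, None] > lmax[None]) & (x[:, None, None] < rmin[None]) & rows[None]
    if dilate > 0:
        band = ndimage.binary_dilation(band, iterations=dilate)
    return band


def latent_difficulty(narrowness: float, cov: ClinicalCovariates, coeffs: LogisticCoefficients,
                      bmi_mean: float = 24.1, bmi_sd: float = 3.4) -> float:
    """Logistic probability that a case is surgically difficult."""
    for value in (coeffs.intercept, coeffs.narrowness, coeffs.male, coeffs.bmi, coeffs.neoadjuvant):
        if not math.isfinite(value):
            raise ValueError("logistic coefficients must be finite")
    bmi_z = (cov.bmi - bmi_mean) / bmi_sd
    lp = (
        coeffs.intercept
        + coeffs.narrowness * narrowness
        + coeffs.male * cov.male
        + coeffs.bmi * bmi_z
        + coeffs.neoadjuvant * cov.neoadjuvant
    )
    return 1.0 / (1.0 + math.exp(-lp))


def _calibrate_intercept(lp_no_intercept: np.ndarray, target: float) -> tuple[float, bool]:
    """Intercept making the cohort's mean logistic probability hit ``target``."""
    lo, hi = -40.0, 40.0

    def mean_p(b0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(lp_no_intercept + b0)))))

    if mean_p(lo) > target or mean_p(hi) < target:
        return (lo if mean_p(lo) > target else hi), False
    for _ in range(200):
        mid = (lo + hi) / 2
        if mean_p(mid) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2, True


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a full labeled cohort: phantoms, covariates, logistic labels, manifest.

    The label mechanism is the logistic model of :func:`latent_difficulty`; no
    extra label-flip noise is added.  With ``target_prevalence`` set, the
    intercept is calibrated so the cohort's expected difficult fraction equals
    the target; an unreachable target leaves a warning in the metadata.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    c = config.coefficients

    widths = config.inlet_mean_mm + config.inlet_sd_mm * np.clip(rng.standard_normal(n), -2.5, 2.5)
    narrowness = (config.inlet_mean_mm - widths) / config.inlet_sd_mm
    male = (rng.random(n) < config.male_rate).astype(int)
    neo = (rng.random(n) < config.neoadjuvant_rate).astype(int)
    bmi = np.clip(config.bmi_mean + config.bmi_sd * rng.standard_normal(n), 12.0, 55.0)
    bmi_z = (bmi - config.bmi_mean) / config.bmi_sd

    lp = c.narrowness * narrowness + c.male * male + c.bmi * bmi_z + c.neoadjuvant * neo
    warnings: list[str] = []
    if config.target_prevalence is not None:
        intercept, ok = _calibrate_intercept(lp, config.target_prevalence)
        if not ok:
            warnings.append(
                f"target prevalence {config.target_prevalence:.3f} unreachable; intercept clamped to {intercept:.1f}"
            )
    else:
        intercept = c.intercept
    probs = 1.0 / (1.0 + np.exp(-(lp + intercept)))
    labels = (rng.random(n) < probs).astype(int)
    phantom_seeds = rng.integers(0, 2**31 - 1, size=n)

    cases: list[LabeledCase] = []
    rows = []
    for i in range(n):
        spec = replace(config.phantom, inlet_width_mm=float(widths[i]))
        volume, spacing = generate_pelvis_phantom(spec, int(phantom_seeds[i]))
        case_id = f"case_{i:04d}"
        cov = ClinicalCovariates(bmi=float(bmi[i]), male=int(male[i]), neoadjuvant=int(neo[i]))
        cases.append(
            LabeledCase(
                case_id=case_id,
                volume=volume,
                spacing_mm=spacing,
                covariates=cov,
                label=int(labels[i]),
                latent_p=float(probs[i]),
                inlet_width_mm=float(widths[i]),
            )
        )
        rows.append(
            {
                "case_id": case_id,
                "label": int(labels[i]),
                "bmi": float(bmi[i]),
                "male": int(male[i]),
                "neoadjuvant": int(neo[i]),
                "path": "",
                "inlet_width_mm": float(widths[i]),
                "latent_p": float(probs[i]),
            }
        )
    manifest = pd.DataFrame(rows)
    meta = {
        "seed": config.seed,
        "intercept_used": float(intercept),
        "warnings": warnings,
        "difficult_fraction": float(labels.mean()),
    }
    return Cohort(cases=cases, manifest=manifest, meta=meta)


def save_cohort(cohort: Cohort, outdir) -> pd.DataFrame:
    """Write each volume as compressed NIfTI plus a manifest CSV; returns the manifest."""
    from pathlib import Path

    from .preprocess import ImageVolume, write_volume

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = cohort.manifest.copy()
    for case in cohort.cases:
        path = outdir / f"{case.case_id}.nii.gz"
        write_volume(ImageVolume(values=case.volume, spacing_mm=case.spacing_mm), path)
        manifest.loc[manifest["case_id"] == case.case_id, "path"] = str(path)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
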