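"""Image normalization and augmentation ahead of the classifier.

The network consumes binary pelvis masks on an isotropic 1.5 mm grid: label
maps are binarized (any bone label -> 1), resampled with nearest-neighbour
interpolation so the {0,1} value contract survives, zero-padded to a common
shape with the content centered, and augmented online with random left-right
flips and small axial rotations.  Clinical covariates are min-max scaled into
the open interval (0,1) using bounds estimated on the training split only.

In-memory arrays are indexed (left-right, anterior-posterior,
inferior-superior); SimpleITK handles NIfTI I/O and resampling, with the
required axis transposition applied at the boundary.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .errors import ConfigurationError, FormatError, MetadataError
from .phantom import ClinicalCovariates, LabeledCase

__all__ = [
    "ImageVolume",
    "ClinicalBounds",
    "read_volume",
    "write_volume",
    "resample_isotropic",
    "binarize_roi",
    "pad_to_common",
    "normalize_clinical",
    "random_flip_lr",
    "random_axial_rotation",
    "augment_epoch",
]

EPS = 1e-3  # open-interval clamp for normalized clinical values


@dataclass
class ImageVolume:
    """A scalar 3D volume with voxel spacing and orientation metadata."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.spacing_mm is None:
            raise MetadataError("voxel spacing is required")
        self.spacing_mm = tuple(float(s) for s in np.atleast_1d(self.spacing_mm)[:3]) if len(
            np.atleast_1d(self.spacing_mm)
        ) >= 3 else tuple([float(np.atleast_1d(self.spacing_mm)[0])] * 3)
        if any(s <= 0 for s in self.spacing_mm):
            raise MetadataError("voxel spacing must be positive on every axis")

    def to_sitk(self) -> sitk.Image:
        # array axes (x,y,z) -> SimpleITK buffer order (z,y,x)
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.values.transpose(2, 1, 0)))
        img.SetSpacing(self.spacing_mm)
        img.SetOrigin(self.origin)
        img.SetDirection(self.direction)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "ImageVolume":
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return cls(
            values=arr,
            spacing_mm=tuple(img.GetSpacing()),
            origin=tuple(img.GetOrigin()),
            direction=tuple(img.GetDirection()),
        )


@dataclass(frozen=True)
class ClinicalBounds:
    """Min-max normalization bounds for BMI, estimated on the training split."""

    bmi_min: float
    bmi_max: float

    @classmethod
    def from_cases(cls, cases: Sequence[LabeledCase]) -> "ClinicalBounds":
        bmis = [c.covariates.bmi for c in cases]
        return cls(bmi_min=float(min(bmis)), bmi_max=float(max(bmis)))


def read_volume(path) -> ImageVolume:
    """Read a NIfTI volume; raises :class:`FormatError` on a malformed file."""
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise FormatError(f"could not read volume at {path}: {exc}") from exc
    return ImageVolume.from_sitk(img)


def write_volume(vol: ImageVolume, path) -> None:
    """Write a volume as NIfTI (.nii / .nii.gz); spacing and orientation round-trip."""
    try:
        sitk.WriteImage(vol.to_sitk(), str(path))
    except RuntimeError as exc:
        raise OSError(f"could not write volume at {path}: {exc}") from exc


def resample_isotropic(vol: ImageVolume, target_mm: float = 1.5, interpolation: str = "nearest") -> ImageVolume:
    """Resample to isotropic ``target_mm`` spacing, preserving physical extent.

    Nearest-neighbour interpolation keeps binary masks binary; an input already
    on the target grid is returned unchanged.
    """
    if interpolation not in ("nearest", "linear"):
        raise ConfigurationError("interpolation must be 'nearest' or 'linear'")
    if np.allclose(vol.spacing_mm, target_mm):
        return copy.deepcopy(vol)
    img = vol.to_sitk()
    new_size = [max(1, int(round(n * s / target_mm))) for n, s in zip(img.GetSize(), img.GetSpacing())]
    interp = sitk.sitkNearestNeighbor if interpolation == "nearest" else sitk.sitkLinear
    out = sitk.Resample(
        img,
        new_size,
        sitk.Transform(),
        interp,
        img.GetOrigin(),
        [target_mm] * 3,
        img.GetDirection(),
        0.0,
        img.GetPixelID(),
    )
    return ImageVolume.from_sitk(out)


def binarize_roi(mask: ImageVolume) -> ImageVolume:
    """Map every nonzero label (all bone classes) to 1 and background to 0."""
    values = np.asarray(mask.values)
    if values.dtype.kind not in "iub":
        if not np.allclose(values, np.round(values)):
            raise ValueError("label volume must contain integers")
    out = (values != 0).astype(np.uint8)
    return ImageVolume(values=out, spacing_mm=mask.spacing_mm, origin=mask.origin, direction=mask.direction)


def pad_to_common(volumes: Sequence[ImageVolume], pad_value: float = 0.0) -> list[ImageVolume]:
    """Zero-pad every volume to the elementwise-maximum shape, content centered."""
    spacings = {tuple(np.round(v.spacing_mm, 9)) for v in volumes}
    if len(spacings) > 1:
        raise ConfigurationError("volumes must share voxel spacing before padding")
    target = np.max([v.values.shape for v in volumes], axis=0)
    out = []
    for v in volumes:
        before = [(t - s) // 2 for t, s in zip(target, v.values.shape)]
        after = [t - s - b for t, s, b in zip(target, v.values.shape, before)]
        padded = np.pad(v.values, list(zip(before, after)), constant_values=pad_value)
        out.append(ImageVolume(values=padded, spacing_mm=v.spacing_mm, origin=v.origin, direction=v.direction))
    return out


def pad_to_shape(values: np.ndarray, shape: tuple[int, int, int], pad_value: float = 0.0) -> np.ndarray:
    """Center-pad (or center-crop) a raw array to an exact shape."""
    out = values
    # crop first where too large
    slices = []
    for s, t in zip(out.shape, shape):
        if s > t:
            start = (s - t) // 2
            slices.append(slice(start, start + t))
        else:
            slices.append(slice(None))
    out = out[tuple(slices)]
    before = [(t - s) // 2 for t, s in zip(shape, out.shape)]
    after = [t - s - b for t, s, b in zip(shape, out.shape, before)]
    return np.pad(out, list(zip(before, after)), constant_values=pad_value)


def normalize_clinical(raw: ClinicalCovariates, bounds: ClinicalBounds, eps: float = EPS) -> np.ndarray:
    """Scale (BMI, male, neoadjuvant) into the open interval (0,1).

    BMI is min-max scaled with the training-split bounds and clamped to
    [eps, 1-eps]; binary flags map to {eps, 1-eps}.
    """
    if bounds.bmi_max <= bounds.bmi_min:
        raise ConfigurationError("degenerate BMI bounds: min == max")
    bmi = (raw.bmi - bounds.bmi_min) / (bounds.bmi_max - bounds.bmi_min)
    bmi = float(np.clip(bmi, eps, 1 - eps))
    flag = lambda b: 1 - eps if b else eps
    return np.array([bmi, flag(raw.male), flag(raw.neoadjuvant)], dtype=np.float64)


def random_flip_lr(values: np.ndarray, p: float = 0.5, rng: np.random.Generator | None = None) -> np.ndarray:
    """With probability ``p``, reverse the left-right axis (axis 0)."""
    rng = rng or np.random.default_rng()
    if p > 0 and rng.random() < p:
        return values[::-1].copy()
    return values.copy()


def random_axial_rotation(
    values: np.ndarray,
    max_deg: float = 5.0,
    p: float = 0.4,
    rng: np.random.Generator | None = None,
    angle_deg: float | None = None,
) -> np.ndarray:
    """With probability ``p``, rotate about the inferior-superior axis.

    The angle is uniform in [-max_deg, +max_deg] around the grid center.
    Binary inputs use nearest-neighbour interpolation and stay binary; a zero
    angle reproduces the input exactly.  ``angle_deg`` forces a specific angle
    (probability gate bypassed), which the tests use.
    """
    rng = rng or np.random.default_rng()
    if angle_deg is None:
        if p <= 0 or rng.random() >= p:
            return values.copy()
        angle_deg = float(rng.uniform(-max_deg, max_deg))
    if angle_deg == 0.0:
        return values.copy()
    is_binary = np.isin(np.unique(values), (0, 1)).all()
    order = 0 if is_binary else 1
    out = ndimage.rotate(values, angle_deg, axes=(0, 1), reshape=False, order=order, mode="constant", cval=0)
    return out.astype(values.dtype, copy=False)


def augment_epoch(
    cases: Iterable[LabeledCase],
    rng: np.random.Generator,
    n_copies: int = 4,
    p_flip: float = 0.5,
    p_rot: float = 0.4,
    max_deg: float = 5.0,
) -> list[LabeledCase]:
    """Per-epoch online augmentation: each case yields ``n_copies`` variants.

    Labels and covariates are copied unchanged; only the volume is perturbed.
    """
    out: list[LabeledCase] = []
    for case in cases:
        for j in range(n_copies):
            vol = random_flip_lr(case.volume, p=p_flip, rng=rng)
            vol = random_axial_rotation(vol, max_deg=max_deg, p=p_rot, rng=rng)
            out.append(
                LabeledCase(
                    case_id=f"{case.case_id}_aug{j}",
                    volume=vol,
                    spacing_mm=case.spacing_mm,
                    covariates=case.covariates,
                    label=case.label,
                    latent_p=case.latent_p,
                    inlet_width_mm=case.inlet_width_mm,
                )
            )
    return out
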