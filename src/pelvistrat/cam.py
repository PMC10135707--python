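"""Attention visualization: 3D GradCAM++, registration-based averaging, highlighting.

GradCAM++ turns the feature map ``f`` and gradient map ``g`` of a selected
network stage into a nonnegative saliency volume:

    alpha   = g^2 / (2 g^2 + sum_xyz(f * g^3))        (zeros in the denominator
                                                       replaced by ones)
    w_c     = sum_xyz(alpha * relu(g))                 per-channel weight
    heatmap = relu(sum_c w_c * f_c)

The layer-resolution heatmap is upsampled trilinearly to the network-input
grid.  To pool attention across a cohort, every case is warped to a common
reference with Demons non-rigid registration (SimpleITK) and the voxelwise
mean skeleton and mean heatmap are reported; the voxels carrying the top
fraction (default 0.5%) of heat are highlighted as a binary mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .errors import ConfigurationError
from .model import DifficultyNet

__all__ = [
    "CamTensors",
    "capture_layer",
    "gradcampp_alpha",
    "gradcampp_heatmap",
    "upsample_heatmap",
    "case_heatmap",
    "demons_register",
    "average_heatmap",
    "top_fraction_highlight",
    "export_heatmap",
]


@dataclass
class CamTensors:
    """Feature map ``f`` and gradient map ``g`` of a selected layer, shape (C, D, H, W)."""

    f: np.ndarray
    g: np.ndarray

    def __post_init__(self) -> None:
        if self.f.shape != self.g.shape:
            raise ValueError("feature and gradient maps must share a shape")


def capture_layer(model: DifficultyNet, layer_tag: str, volume: np.ndarray, clinical: np.ndarray,
                  target: str = "predicted") -> tuple[CamTensors, float]:
    """One forward + one backward pass recording f and g at ``layer_tag``.

    The backward pass differentiates the logit of the predicted class (the
    negated logit when the prediction is non-difficult); ``target='difficult'``
    forces the difficult-class logit.  Returns the captured tensors and the
    prediction score.
    """
    was_training = model.training
    model.eval()
    res = model.forward(volume[None], np.asarray(clinical).reshape(1, -1))
    if layer_tag not in res.stages:
        raise ConfigurationError(f"unknown layer tag {layer_tag!r}; available: {sorted(res.stages)}")
    score = float(res.score.data.reshape(-1)[0])
    sign = 1.0
    if target == "predicted" and score < 0.5:
        sign = -1.0
    elif target not in ("predicted", "difficult"):
        raise ConfigurationError("target must be 'predicted' or 'difficult'")
    res.logit.backward(np.full_like(res.logit.data, sign))
    stage = res.stages[layer_tag]
    g = stage.grad if stage.grad is not None else np.zeros_like(stage.data)
    if was_training:
        model.train()
    return CamTensors(f=stage.data[0].copy(), g=np.asarray(g, dtype=np.float32)[0].copy()), score


def gradcampp_alpha(t: CamTensors) -> np.ndarray:
    """GradCAM++ alpha weights, zero wherever the gradient map is zero."""
    if not (np.isfinite(t.f).all() and np.isfinite(t.g).all()):
        raise ValueError("feature/gradient maps must be finite")
    g2 = t.g.astype(np.float64) ** 2
    g3 = g2 * t.g
    denom = 2.0 * g2 + np.sum(t.f * g3, axis=(1, 2, 3), keepdims=True)
    denom = np.where(denom == 0.0, 1.0, denom)
    return g2 / denom


def gradcampp_heatmap(t: CamTensors, alpha: np.ndarray) -> np.ndarray:
    """Layer-resolution heatmap: sum_c [sum_xyz(alpha * relu(g))] * f_c, clamped at 0."""
    weights = np.sum(alpha * np.maximum(t.g, 0.0), axis=(1, 2, 3))
    heat = np.tensordot(weights, t.f.astype(np.float64), axes=(0, 0))
    return np.maximum(heat, 0.0)


def upsample_heatmap(heat: np.ndarray, input_shape: Sequence[int]) -> np.ndarray:
    """Trilinear upsampling of a layer-resolution heatmap to the input grid.

    Grid-aligned convention: each coarse cell is treated as a uniform block of
    the fine grid (``grid_mode=True``), so a constant map stays constant and
    total mass is approximately preserved for smooth inputs.  Equal shapes are
    an identity.
    """
    input_shape = tuple(input_shape)
    if heat.shape == input_shape:
        return heat.copy()
    factors = [t / s for t, s in zip(input_shape, heat.shape)]
    out = ndimage.zoom(heat.astype(np.float64), factors, order=1, mode="nearest", grid_mode=True)
    # zoom can over/undershoot the requested size by a voxel on ratio edge cases
    assert out.shape == input_shape, (out.shape, input_shape)
    return np.maximum(out, 0.0)


def case_heatmap(model: DifficultyNet, volume: np.ndarray, clinical: np.ndarray,
                 layer_tag: str = "layer4", target: str = "predicted") -> np.ndarray:
    """End-to-end per-case saliency: capture, alpha, heatmap, upsample."""
    tensors, _ = capture_layer(model, layer_tag, volume, clinical, target=target)
    alpha = gradcampp_alpha(tensors)
    heat = gradcampp_heatmap(tensors, alpha)
    return upsample_heatmap(heat, volume.shape)


def _to_float_image(arr: np.ndarray, spacing) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)).astype(np.float32))
    img.SetSpacing(tuple(float(s) for s in np.broadcast_to(np.atleast_1d(spacing), (3,))))
    return img


def demons_register(
    moving: np.ndarray,
    fixed: np.ndarray,
    spacing=1.0,
    iterations: int = 100,
    smoothing_sigma: float = 1.5,
    presmooth_sigma: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Demons non-rigid registration of ``moving`` onto ``fixed``.

    Binary masks are Gaussian-smoothed before the intensity-driven Demons
    update so boundary gradients extend into the gap between surfaces.
    Returns ``(field, warped)``: the dense displacement field with vector
    components as the last axis (array-index units, mapping fixed-space points
    into moving space) and the warped moving volume (nearest-neighbour, binary
    preserved).
    """
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed volumes must share a shape")
    mov = _to_float_image(np.asarray(moving, dtype=np.float32), spacing)
    fix = _to_float_image(np.asarray(fixed, dtype=np.float32), spacing)
    if presmooth_sigma > 0:
        mov_s = sitk.SmoothingRecursiveGaussian(mov, [presmooth_sigma * s for s in mov.GetSpacing()])
        fix_s = sitk.SmoothingRecursiveGaussian(fix, [presmooth_sigma * s for s in fix.GetSpacing()])
    else:
        mov_s, fix_s = mov, fix
    demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
    demons.SetNumberOfIterations(int(iterations))
    demons.SetSmoothDisplacementField(True)
    demons.SetStandardDeviations(smoothing_sigma)
    field_img = demons.Execute(fix_s, mov_s)

    warped_img = sitk.Resample(mov, fix, sitk.DisplacementFieldTransform(sitk.Image(field_img)),
                               sitk.sitkNearestNeighbor, 0.0, mov.GetPixelID())
    warped = sitk.GetArrayFromImage(warped_img).transpose(2, 1, 0)
    field = sitk.GetArrayFromImage(field_img)  # (z, y, x, 3) with (x,y,z) physical components
    field = field.transpose(2, 1, 0, 3)
    sp = np.broadcast_to(np.atleast_1d(spacing), (3,))
    field = field / sp  # physical mm -> voxel units per component
    return field.astype(np.float32), warped.astype(moving.dtype)


def warp_with_field(values: np.ndarray, field: np.ndarray, spacing=1.0, interpolation: str = "linear") -> np.ndarray:
    """Apply a displacement field from :func:`demons_register` to another volume."""
    sp = np.broadcast_to(np.atleast_1d(spacing).astype(float), (3,))
    field_mm = (field * sp).transpose(2, 1, 0, 3).astype(np.float64)
    field_img = sitk.GetImageFromArray(field_mm, isVector=True)
    field_img.SetSpacing(tuple(sp))
    img = _to_float_image(np.asarray(values, dtype=np.float32), sp)
    interp = sitk.sitkLinear if interpolation == "linear" else sitk.sitkNearestNeighbor
    out = sitk.Resample(img, img, sitk.DisplacementFieldTransform(field_img), interp, 0.0)
    return sitk.GetArrayFromImage(out).transpose(2, 1, 0)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = float(np.sum((a > 0) & (b > 0)))
    total = float(np.sum(a > 0) + np.sum(b > 0))
    return 2 * inter / total if total > 0 else 1.0


def pick_reference(volumes: Sequence[np.ndarray]) -> int:
    """Cohort-averaging reference: the case with median foreground voxel count."""
    counts = np.array([int(v.sum()) for v in volumes])
    order = np.argsort(counts, kind="stable")
    return int(order[len(order) // 2])


def average_heatmap(
    volumes: Sequence[np.ndarray],
    heatmaps: Sequence[np.ndarray],
    reference_index: int | None = None,
    spacing=1.0,
    iterations: int = 100,
    smoothing_sigma: float = 1.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Warp every case (and its heatmap, with the same field) onto a reference
    and return the voxelwise mean skeleton and mean heatmap."""
    if len(volumes) == 0:
        raise ValueError("at least one case is required")
    if reference_index is None:
        reference_index = pick_reference(volumes)
    ref = volumes[reference_index]
    skeletons, heats = [], []
    for i, (vol, heat) in enumerate(zip(volumes, heatmaps)):
        if i == reference_index:
            skeletons.append(vol.astype(np.float64))
            heats.append(np.asarray(heat, dtype=np.float64))
            continue
        field, warped = demons_register(vol, ref, spacing=spacing, iterations=iterations,
                                        smoothing_sigma=smoothing_sigma)
        skeletons.append(warped.astype(np.float64))
        heats.append(warp_with_field(heat, field, spacing=spacing, interpolation="linear"))
    return np.mean(skeletons, axis=0), np.mean(heats, axis=0)


def top_fraction_highlight(heat: np.ndarray, count: int | None = None, fraction: float | None = None) -> np.ndarray:
    """Binary mask of exactly the ``count`` hottest voxels.

    ``fraction`` gives ``count = round(fraction * n_voxels)``.  Ties at the
    cutoff break by lexicographic voxel index, so the mask is deterministic.
    """
    if count is None:
        if fraction is None:
            fraction = 0.005
        count = int(round(fraction * heat.size))
    if count > heat.size:
        raise ValueError("count exceeds the number of voxels")
    flat = heat.reshape(-1)
    order = np.argsort(-flat, kind="stable")  # stable: ties keep lexicographic order
    mask = np.zeros(heat.size, dtype=bool)
    mask[order[:count]] = True
    return mask.reshape(heat.shape)


def export_heatmap(heat: np.ndarray, out_prefix, spacing=1.0, colormap: str = "jet") -> list[Path]:
    """Write the raw heatmap as NIfTI plus JET-mapped mid-plane PNG snapshots.

    The color mapping is min-max over the heatmap, so the coldest voxel maps
    to the first JET color and the hottest to the last.
    """
    import matplotlib

    matplotlib.use("Agg")
    from PIL import Image

    from .preprocess import ImageVolume, write_volume

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    sp = tuple(np.broadcast_to(np.atleast_1d(spacing).astype(float), (3,)))
    nii_path = out_prefix.with_suffix(".nii.gz")
    write_volume(ImageVolume(values=heat.astype(np.float32), spacing_mm=sp), nii_path)
    paths = [nii_path]
    lo, hi = float(heat.min()), float(heat.max())
    norm = (heat - lo) / (hi - lo) if hi > lo else np.zeros_like(heat)
    mapper = matplotlib.colormaps[colormap]
    for axis, name in enumerate(("sagittal", "coronal", "axial")):
        sl = [slice(None)] * 3
        sl[axis] = heat.shape[axis] // 2
        rgba = mapper(norm[tuple(sl)])
        png_path = out_prefix.parent / f"{out_prefix.name}_{name}.png"
        Image.fromarray((rgba[..., :3] * 255).astype(np.uint8)).save(png_path)
        paths.append(png_path)
    return paths
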