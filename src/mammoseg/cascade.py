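"""Sliding-window patch inference with center-weighted fusion, largest
connected-component post-processing, and the two-step gland -> lesion
cascade.

Step 1 segments the mammary gland on the resampled, z-scored volume; the
prediction is reduced to its largest connected component and its bounding
box (plus margin) is cropped. Step 2 z-scores the crop only and segments
the lesion inside it, again keeping the largest component, before mapping
back to the original grid. Confounders outside the gland (the heart, whose
intensity is deliberately similar to lesions) are thereby excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import ImageVolume, LabelMask
from .preprocess import resample, zscore_normalize

__all__ = [
    "PatchGrid",
    "make_patch_grid",
    "gaussian_weight_map",
    "sliding_window_predict",
    "largest_component",
    "crop_to_mask",
    "run_two_step",
    "CascadeConfig",
    "CascadeError",
]


class CascadeError(RuntimeError):
    """A cascade stage produced an unusable intermediate result."""


@dataclass
class PatchGrid:
    patch_size: int
    stride: int
    origins: list[tuple[int, int, int]]


def _axis_origins(length: int, patch: int, stride: int) -> list[int]:
    origins = list(range(0, length - patch + 1, stride))
    if origins[-1] + patch < length:
        origins.append(length - patch)  # end-aligned final patch
    return origins


def make_patch_grid(vol_shape, patch_size: int) -> PatchGrid:
    """Tile a volume with ``patch_size`` cubes overlapping by half a patch
    (stride = patch_size / 2), end-aligned at each axis boundary."""
    if patch_size % 2 != 0:
        raise ValueError(f"patch size must be even, got {patch_size}")
    if any(patch_size > s for s in vol_shape):
        raise ValueError(f"patch {patch_size} exceeds volume shape {tuple(vol_shape)}")
    stride = patch_size // 2
    per_axis = [_axis_origins(s, patch_size, stride) for s in vol_shape]
    origins = [(a, b, c) for a in per_axis[0] for b in per_axis[1] for c in per_axis[2]]
    return PatchGrid(patch_size=patch_size, stride=stride, origins=origins)


def gaussian_weight_map(patch_size: int, sigma_fraction: float = 0.125) -> np.ndarray:
    """Separable Gaussian fusion weights, maximal at the patch center,
    floored at 1e-3 of the maximum so every voxel keeps positive weight."""
    if sigma_fraction <= 0:
        raise ValueError("sigma_fraction must be positive")
    x = np.arange(patch_size) - (patch_size - 1) / 2.0
    g = np.exp(-0.5 * (x / (sigma_fraction * patch_size)) ** 2)
    w = g[:, None, None] * g[None, :, None] * g[None, None, :]
    return np.maximum(w, 1e-3 * w.max())


def sliding_window_predict(model, vol: ImageVolume, grid: PatchGrid | None = None,
                           weights: np.ndarray | None = None) -> np.ndarray:
    """Fuse per-patch softmax predictions into a (K, D, H, W) probability
    map: each voxel's probability is the weight-averaged patch prediction,
    renormalized to sum to one across classes."""
    data = np.asarray(vol.data, dtype=float)
    if grid is None:
        grid = make_patch_grid(data.shape, model.config.patch_size)
    if weights is None:
        weights = gaussian_weight_map(grid.patch_size)
    if weights.shape != (grid.patch_size,) * 3:
        raise ValueError("weight map shape must match the patch size")
    ps = grid.patch_size
    acc = None
    wsum = np.zeros(data.shape)
    for o in grid.origins:
        sl = tuple(slice(i, i + ps) for i in o)
        probs = model.predict_proba(data[sl])
        if acc is None:
            acc = np.zeros((probs.shape[0],) + data.shape)
        acc[(slice(None),) + sl] += probs * weights
        wsum[sl] += weights
    if acc is None or (wsum == 0).any():
        raise CascadeError("patch grid does not cover the volume")
    fused = acc / wsum
    return fused / fused.sum(axis=0, keepdims=True)


def largest_component(mask: LabelMask, connectivity: int = 3) -> LabelMask:
    """Keep only the largest foreground component (26-connected by
    default); equal-size ties go to the lowest-labelled component."""
    structure = ndimage.generate_binary_structure(3, connectivity)
    labels, n = ndimage.label(mask.data > 0, structure=structure)
    if n == 0:
        return mask.with_data(np.zeros_like(mask.data))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = 1 + int(np.argmax(sizes))  # argmax takes the first (lowest) on ties
    return mask.with_data((labels == keep).astype(mask.data.dtype))


def crop_to_mask(vol: ImageVolume, mask: LabelMask, margin_mm: float = 0.0):
    """Axis-aligned bounding-box crop of the mask's support, expanded by a
    physical margin and clipped to the volume. Returns (crop, offset)."""
    fg = np.argwhere(mask.data > 0)
    if len(fg) == 0:
        raise CascadeError("cannot crop to an empty mask")
    lo = fg.min(axis=0)
    hi = fg.max(axis=0) + 1
    margin_vox = [int(np.ceil(margin_mm / s)) for s in vol.spacing]
    lo = np.maximum(lo - margin_vox, 0)
    hi = np.minimum(hi + margin_vox, vol.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    crop = ImageVolume(data=vol.data[sl].copy(), spacing=vol.spacing, origin=vol.origin)
    return crop, tuple(int(x) for x in lo)


@dataclass
class CascadeConfig:
    target_spacing: tuple[float, float, float] | None = None
    margin_mm: float = 5.0
    sigma_fraction: float = 0.125


def run_two_step(vol: ImageVolume, gland_model, lesion_model,
                 config: CascadeConfig | None = None) -> LabelMask:
    """Full two-step inference; the returned lesion mask lives on the
    input volume's grid."""
    config = config or CascadeConfig()
    work = vol
    if config.target_spacing is not None:
        work = resample(vol, config.target_spacing, mode="image")
    normed = zscore_normalize(work)

    gprobs = sliding_window_predict(
        gland_model, normed,
        weights=gaussian_weight_map(gland_model.config.patch_size, config.sigma_fraction),
    )
    gland = LabelMask(
        data=(np.argmax(gprobs, axis=0) == 1).astype(np.uint8),
        spacing=normed.spacing,
    )
    if gland.data.sum() == 0:
        raise CascadeError("gland segmentation (step 1) produced an empty mask")
    gland = largest_component(gland)

    crop, offset = crop_to_mask(work, gland, margin_mm=config.margin_mm)
    gland_crop = gland.data[
        tuple(slice(o, o + s) for o, s in zip(offset, crop.shape))
    ]
    ps = lesion_model.config.patch_size
    pad = [max(0, ps - s) for s in crop.shape]
    if any(pad):
        crop = crop.with_data(
            np.pad(crop.data, [(0, p) for p in pad], mode="edge")
        )
        gland_crop = np.pad(gland_crop, [(0, p) for p in pad])
    crop_normed = zscore_normalize(crop)  # step 2: z-score only

    lprobs = sliding_window_predict(
        lesion_model, crop_normed,
        weights=gaussian_weight_map(ps, config.sigma_fraction),
    )
    # the lesion is sought within the gland region: voxels outside the
    # predicted gland are background by construction
    lesion_crop = LabelMask(
        data=((np.argmax(lprobs, axis=0) == 1) & (gland_crop > 0)).astype(np.uint8),
        spacing=crop.spacing,
    )
    if lesion_crop.data.sum() > 0:
        lesion_crop = largest_component(lesion_crop)

    out_work = np.zeros(work.shape, dtype=np.uint8)
    core = tuple(
        slice(o, min(o + cs, ws))
        for o, cs, ws in zip(offset, lesion_crop.shape, work.shape)
    )
    src = tuple(slice(0, s.stop - s.start) for s in core)
    out_work[core] = lesion_crop.data[src]
    work_mask = LabelMask(data=out_work, spacing=work.spacing)

    if config.target_spacing is not None and work.shape != vol.shape:
        back = resample(work_mask, vol.spacing, mode="mask")
        data = back.data
        fixed = np.zeros(vol.shape, dtype=np.uint8)
        sl = tuple(slice(0, min(a, b)) for a, b in zip(vol.shape, data.shape))
        fixed[sl] = data[sl]
        return LabelMask(data=fixed, spacing=vol.spacing, origin=vol.origin)
    return LabelMask(data=out_work, spacing=vol.spacing, origin=vol.origin)
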