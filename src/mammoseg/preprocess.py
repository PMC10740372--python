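"""Resampling to the cohort median spacing, per-patient z-score
normalization, and the five training-time augmentations (rotation, scaling,
elastic deformation, gamma correction, axis inversion/flips).

Spatial transforms are applied identically to the image (trilinear) and to
any paired masks (nearest-neighbor); intensity transforms touch the image
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import ImageVolume, LabelMask, validate_alignment

__all__ = [
    "AugmentParams",
    "compute_median_spacing",
    "resample",
    "zscore_normalize",
    "augment",
]


class NormalizationError(ValueError):
    """Volume has no intensity variance to normalize."""


@dataclass
class AugmentParams:
    rotation_deg: float = 15.0
    scale_range: tuple[float, float] = (0.85, 1.15)
    elastic_alpha_mm: float = 2.0
    elastic_sigma_mm: float = 4.0
    gamma_range: tuple[float, float] = (0.7, 1.5)
    apply_probs: dict = field(
        default_factory=lambda: {
            "rotation": 0.5,
            "scale": 0.5,
            "elastic": 0.3,
            "gamma": 0.3,
            "flip": 0.5,
        }
    )

    def __post_init__(self) -> None:
        if self.scale_range[0] <= 0 or self.gamma_range[0] <= 0:
            raise ValueError("scale and gamma bounds must be positive")
        for name, p in self.apply_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"apply_probs[{name!r}] = {p} outside [0, 1]")


def compute_median_spacing(volumes) -> tuple[float, float, float]:
    """Per-axis median of voxel spacings; lower median for even counts."""
    spacings = np.array([v.spacing for v in volumes], dtype=float)
    if spacings.size == 0:
        raise ValueError("need at least one volume to compute a median spacing")
    lower_median_idx = (spacings.shape[0] - 1) // 2
    return tuple(float(np.sort(spacings[:, a])[lower_median_idx]) for a in range(3))


def resample(vol: ImageVolume, target_spacing, mode: str = "image"):
    """Resample to ``target_spacing`` (mm); trilinear for images,
    nearest-neighbor for masks. Output shape is
    round(shape * spacing / target), floored at 1 voxel per axis."""
    target = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target):
        raise ValueError(f"target spacing must be positive, got {target}")
    if mode not in ("image", "mask"):
        raise ValueError(f"mode must be 'image' or 'mask', got {mode!r}")
    new_shape = tuple(
        max(1, int(round(n * s / t)))
        for n, s, t in zip(vol.shape, vol.spacing, target)
    )
    zoom = [ns / n for ns, n in zip(new_shape, vol.shape)]
    order = 1 if mode == "image" else 0
    data = ndimage.zoom(vol.data.astype(float), zoom, order=order, mode="nearest", grid_mode=True)
    data = data[: new_shape[0], : new_shape[1], : new_shape[2]]
    if mode == "mask":
        return LabelMask(data=np.rint(data).astype(vol.data.dtype), spacing=target, origin=vol.origin)
    return ImageVolume(data=data, spacing=target, origin=vol.origin)


def zscore_normalize(vol: ImageVolume) -> ImageVolume:
    """Zero-mean unit-variance normalization over all voxels of one volume."""
    data = vol.data.astype(float)
    sd = data.std()
    if data.size < 2 or sd == 0:
        raise NormalizationError("cannot z-score a constant (or single-voxel) volume")
    return vol.with_data((data - data.mean()) / sd)


def _rescaled_gamma(data: np.ndarray, gamma: float) -> np.ndarray:
    """Gamma correction on min-max-rescaled intensities, mapped back."""
    lo, hi = data.min(), data.max()
    if hi == lo:
        return data.copy()
    unit = (data - lo) / (hi - lo)
    return unit**gamma * (hi - lo) + lo


def augment(vol: ImageVolume, masks, params: AugmentParams, seed: int):
    """Apply one random draw of the augmentation pipeline.

    ``masks`` is a single LabelMask or a sequence of them; every mask gets
    the identical spatial transform with nearest-neighbor interpolation.
    Order: rotation -> scale -> elastic, then gamma (intensity only); flips
    last (spatial, applied to image and masks). All-zero probabilities give
    the identity. Deterministic in ``seed``.
    """
    single = isinstance(masks, LabelMask)
    mask_list = [masks] if single else list(masks)
    for m in mask_list:
        if not validate_alignment(vol, m):
            raise ValueError("image and mask are not aligned")
    rng = np.random.default_rng(seed)
    p = params.apply_probs

    img = vol.data.astype(float)
    mdatas = [m.data.copy() for m in mask_list]

    # decisions drawn in a fixed order so seed reuse is reproducible
    do_rot = rng.random() < p.get("rotation", 0)
    rot_axis = int(rng.integers(3))
    rot_angle = rng.uniform(-params.rotation_deg, params.rotation_deg)
    do_scale = rng.random() < p.get("scale", 0)
    scale = rng.uniform(*params.scale_range)
    do_elastic = rng.random() < p.get("elastic", 0)
    elastic_seed = int(rng.integers(2**31 - 1))
    do_gamma = rng.random() < p.get("gamma", 0)
    gamma = rng.uniform(*params.gamma_range)
    do_flip = rng.random() < p.get("flip", 0)
    flip_axes = tuple(int(a) for a in range(3) if rng.random() < 0.5)

    if do_rot:
        axes = [(1, 2), (0, 2), (0, 1)][rot_axis]
        img = ndimage.rotate(img, rot_angle, axes=axes, reshape=False, order=1, mode="nearest")
        mdatas = [
            ndimage.rotate(m, rot_angle, axes=axes, reshape=False, order=0, mode="nearest")
            for m in mdatas
        ]
    if do_scale:
        center = (np.asarray(img.shape) - 1) / 2.0
        mat = np.eye(3) / scale
        offset = center - mat @ center
        img = ndimage.affine_transform(img, mat, offset=offset, order=1, mode="nearest")
        mdatas = [
            ndimage.affine_transform(m, mat, offset=offset, order=0, mode="nearest")
            for m in mdatas
        ]
    if do_elastic:
        erng = np.random.default_rng(elastic_seed)
        sigma_vox = [params.elastic_sigma_mm / s for s in vol.spacing]
        disp = [
            ndimage.gaussian_filter(erng.normal(0, 1, img.shape), sigma_vox)
            for _ in range(3)
        ]
        disp = [
            d / (np.abs(d).max() + 1e-12) * (params.elastic_alpha_mm / s)
            for d, s in zip(disp, vol.spacing)
        ]
        coords = np.meshgrid(*[np.arange(s) for s in img.shape], indexing="ij")
        warped = [c + d for c, d in zip(coords, disp)]
        img = ndimage.map_coordinates(img, warped, order=1, mode="nearest")
        mdatas = [ndimage.map_coordinates(m, warped, order=0, mode="nearest") for m in mdatas]
    if do_gamma:
        img = _rescaled_gamma(img, gamma)
    if do_flip and flip_axes:
        img = np.flip(img, axis=flip_axes)
        mdatas = [np.flip(m, axis=flip_axes) for m in mdatas]

    out_vol = vol.with_data(np.ascontiguousarray(img))
    out_masks = [
        LabelMask(
            data=np.ascontiguousarray(np.rint(m)).astype(om.data.dtype),
            spacing=om.spacing,
            origin=om.origin,
        )
        for m, om in zip(mdatas, mask_list)
    ]
    return out_vol, (out_masks[0] if single else out_masks)
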