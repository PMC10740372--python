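"""Domain containers and NIfTI/CSV input-output.

Volumes and label masks are 3D grids with physical voxel spacing in mm;
cohorts are per-patient tables of molecular markers (HER2, ER, PR, Ki-67),
a binary pathologic-complete-response (pCR) label, an acquisition-center id
and file references. All geometric code downstream works in physical mm
via the spacing carried here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ImageVolume",
    "LabelMask",
    "PatientRecord",
    "CohortTable",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
    "load_cohort",
    "save_cohort",
    "validate_alignment",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = [
    "patient_id",
    "her2",
    "er",
    "pr",
    "ki67",
    "pcr_label",
    "center_id",
    "image_path",
    "gland_mask_path",
    "lesion_mask_path",
]


class SchemaError(ValueError):
    """Cohort file lacks a required column."""


class ValidationError(ValueError):
    """A field value violates its invariant."""


@dataclass
class ImageVolume:
    """A 3D scalar intensity grid with per-axis voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must have 3 axes, got {self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("every axis must have length >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "ImageVolume":
        return replace(self, data=self.data.copy())

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        return replace(self, data=data)


@dataclass
class LabelMask(ImageVolume):
    """Integer class labels on the same grid as a paired :class:`ImageVolume`.

    Label 0 is background.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("mask data must be an integer dtype")
        if self.data.min() < 0:
            raise ValueError("mask labels must be nonnegative")


@dataclass
class PatientRecord:
    patient_id: str
    her2: int
    er: int
    pr: int
    ki67: float
    pcr_label: int
    center_id: str
    image_path: str = ""
    gland_mask_path: str = ""
    lesion_mask_path: str = ""

    def __post_init__(self) -> None:
        for name in ("her2", "er", "pr", "pcr_label"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValidationError(
                    f"patient {self.patient_id!r}: {name}={v!r} must be 0 or 1"
                )
        if not 0.0 <= float(self.ki67) <= 1.0:
            raise ValidationError(
                f"patient {self.patient_id!r}: ki67={self.ki67!r} outside [0, 1]"
            )


@dataclass
class CohortTable:
    """Ordered collection of patient records with unique patient ids."""

    records: list[PatientRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PatientRecord:
        return self.records[i]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records], columns=COHORT_COLUMNS)


def _affine_from_spacing(spacing: Sequence[float], origin: Sequence[float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_volume(vol: ImageVolume, path: str | os.PathLike) -> None:
    """Write a volume (or mask) as NIfTI-1; masks keep their integer dtype."""
    path = Path(path)
    data = vol.data
    if isinstance(vol, LabelMask):
        data = data.astype(np.uint8 if data.max(initial=0) < 256 else np.int16)
    img = nib.Nifti1Image(data, _affine_from_spacing(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


save_mask = save_volume


def load_volume(path: str | os.PathLike) -> ImageVolume:
    """Read a NIfTI volume; spacing comes from the header zooms."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {data.ndim} axes")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return ImageVolume(data=data, spacing=spacing, origin=origin)


def load_mask(path: str | os.PathLike) -> LabelMask:
    vol = load_volume(path)
    data = vol.data
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise ValueError(f"{path}: mask voxels are not integers")
        data = rounded.astype(np.int32)
    return LabelMask(data=data, spacing=vol.spacing, origin=vol.origin)


def validate_alignment(vol: ImageVolume, mask: ImageVolume, rtol: float = 1e-4) -> bool:
    """True iff shapes match and spacings agree within relative tolerance."""
    if vol.shape != mask.shape:
        return False
    return bool(
        np.allclose(np.asarray(vol.spacing), np.asarray(mask.spacing), rtol=rtol, atol=0)
    )


def load_cohort(path: str | os.PathLike) -> CohortTable:
    """Read a cohort CSV with the documented fixed header.

    Raises :class:`SchemaError` on a missing column and
    :class:`ValidationError` on out-of-range values or duplicate ids,
    naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such cohort file: {path}")
    df = pd.read_csv(path, dtype={"patient_id": str, "center_id": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                PatientRecord(
                    patient_id=str(row["patient_id"]),
                    her2=int(row["her2"]),
                    er=int(row["er"]),
                    pr=int(row["pr"]),
                    ki67=float(row["ki67"]),
                    pcr_label=int(row["pcr_label"]),
                    center_id=str(row["center_id"]),
                    image_path=str(row["image_path"]),
                    gland_mask_path=str(row["gland_mask_path"]),
                    lesion_mask_path=str(row["lesion_mask_path"]),
                )
            )
        except ValidationError as e:
            raise ValidationError(f"{path} row {idx}: {e}") from e
    return CohortTable(records=records)


def save_cohort(cohort: CohortTable, path: str | os.PathLike) -> None:
    cohort.to_dataframe().to_csv(path, index=False)
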