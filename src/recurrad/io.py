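"""Image and table containers plus NRRD/NIfTI round-tripping.

The in-memory image container is a thin (array, spacing) pair: CT volumes
are Hounsfield-unit scalar grids indexed ``(z, y, x)`` with physical voxel
spacing in millimetres per axis, and tumor masks are aligned boolean grids.
Disk formats are delegated to SimpleITK.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk

__all__ = [
    "ImageVolume",
    "read_image",
    "write_image",
    "write_mask",
    "read_clinical_table",
    "write_clinical_table",
    "CLINICAL_COLUMNS",
]

#: canonical column order of the clinical CSV
CLINICAL_COLUMNS = [
    "subject_id",
    "time_dm",
    "event_dm",
    "time_lrr",
    "event_lrr",
    "n_fractions",
    "dose_per_fraction",
    "bed",
]


@dataclass
class ImageVolume:
    """A 3D scalar grid with physical voxel spacing.

    Parameters
    ----------
    array : numpy.ndarray
        Voxel values, indexed ``(z, y, x)``.
    spacing : tuple of float
        Millimetres per voxel along ``(z, y, x)``.
    """

    array: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array)
        if self.array.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.array.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.array.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.array.copy(), self.spacing, dict(self.meta))


def _to_sitk(vol: ImageVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(vol.array)
    # SimpleITK spacing is (x, y, z); our arrays are (z, y, x)
    img.SetSpacing(tuple(vol.spacing[::-1]))
    return img


def read_image(path: str | Path) -> ImageVolume:
    """Read an NRRD or NIfTI scalar volume into an :class:`ImageVolume`."""
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got ndim={arr.ndim}")
    return ImageVolume(arr, spacing=tuple(img.GetSpacing())[::-1])


def write_image(vol: ImageVolume, path: str | Path) -> None:
    """Write a volume as NRRD or NIfTI (format chosen by extension)."""
    sitk.WriteImage(_to_sitk(vol), str(path), useCompression=False)


def write_mask(mask: np.ndarray, spacing: tuple[float, float, float], path: str | Path) -> None:
    """Write a binary mask as an unsigned 8-bit label map."""
    vol = ImageVolume(np.asarray(mask, dtype=np.uint8), spacing)
    write_image(vol, path)


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    return df


def write_clinical_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=[c for c in CLINICAL_COLUMNS if c in df.columns])
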