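"""Resampling to the 1 mm isotropic analysis grid and gray-level binning.

Texture matrices require a discretized image: raw HU values inside the tumor
mask are binned with a fixed 25 HU width anchored at the mask minimum, so a
constant HU shift of the scan leaves the binned volume unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import ImageVolume

__all__ = ["DiscretizationSpec", "resample_isotropic", "discretize"]


@dataclass(frozen=True)
class DiscretizationSpec:
    """Fixed-bin-width gray-level discretization, anchored at the mask minimum."""

    bin_width: float = 25.0  # HU

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")


def resample_isotropic(
    volume: ImageVolume,
    mask: np.ndarray,
    target_spacing: float = 1.0,
) -> tuple[ImageVolume, np.ndarray]:
    """Resample image (tricubic) and mask (nearest-neighbour) to isotropic spacing.

    Cubic spline interpolation is applied per axis to the intensities; the
    mask is resampled with order-0 interpolation so it stays strictly binary.
    The physical extent of the grid is preserved to within one voxel.
    """
    if volume.array.shape != mask.shape:
        raise ValueError("volume and mask are not aligned")
    factors = tuple(s / target_spacing for s in volume.spacing)
    if all(abs(f - 1.0) < 1e-9 for f in factors):
        out = ImageVolume(volume.array.copy(), (target_spacing,) * 3)
        out.meta["original_spacing"] = volume.spacing
        out.meta["interpolator"] = "identity"
        return out, mask.astype(bool).copy()

    arr = ndimage.zoom(volume.array.astype(float), factors, order=3, mode="nearest", grid_mode=True)
    m = ndimage.zoom(mask.astype(np.uint8), factors, order=0, mode="nearest", grid_mode=True)
    out = ImageVolume(arr, (target_spacing,) * 3)
    out.meta["original_spacing"] = volume.spacing
    out.meta["interpolator"] = "cubic-spline"
    return out, m.astype(bool)


def discretize(
    volume: ImageVolume | np.ndarray,
    mask: np.ndarray,
    spec: DiscretizationSpec = DiscretizationSpec(),
) -> np.ndarray:
    """Bin masked intensities: ``bin = floor((x - min_mask) / W) + 1``.

    Returns an integer volume where voxels outside the mask are 0 and masked
    voxels carry bin indices starting at 1; the number of gray levels is the
    maximum bin. Bins are half-open ``[min + (k-1)W, min + kW)``.
    """
    arr = volume.array if isinstance(volume, ImageVolume) else np.asarray(volume)
    if arr.shape != mask.shape:
        raise ValueError("volume and mask are not aligned")
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    vals = arr[mask].astype(float)
    bins = np.floor((vals - vals.min()) / spec.bin_width).astype(np.int64) + 1
    out = np.zeros(arr.shape, dtype=np.int64)
    out[mask] = bins
    return out
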