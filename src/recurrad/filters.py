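"""Wavelet-subband and Laplacian-of-Gaussian image variants.

Feature names carry a filter prefix: ``Wv LLL``..``Wv HHH`` are the eight
subbands of a single-level undecimated (stationary) 3D wavelet transform,
and ``LoG 3mm 2D/3D`` are Laplacian-of-Gaussian responses at sigma = 3 mm
computed slice-wise or volumetrically. Every output shares the input grid,
so masks transfer unchanged.

Configurable knobs (wavelet family, LoG sigma, boundary mode) live in
:data:`FILTER_CONFIG`; the defaults are pinned for reproducibility.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pywt
from scipy import ndimage

from .io import ImageVolume

__all__ = ["FILTER_CONFIG", "wavelet_subbands", "log_filter", "filter_bank"]

FILTER_CONFIG = {
    "wavelet.family": "coif1",
    "log.sigma_mm": 3.0,
    "log.modes": ("2D", "3D"),
    "boundary": "reflect",  # symmetric padding
}

#: subband names in (x, y, z) letter order, e.g. "HLL" = high-pass x
SUBBAND_NAMES = ["".join(s) for s in product("LH", repeat=3)]


def _wavelet_filters(family: str) -> tuple[np.ndarray, np.ndarray]:
    w = pywt.Wavelet(family)
    return np.asarray(w.dec_lo), np.asarray(w.dec_hi)


def wavelet_subbands(volume: ImageVolume | np.ndarray) -> dict[str, np.ndarray]:
    """Single-level undecimated 3D wavelet transform.

    Returns the eight subbands keyed ``LLL``..``HHH`` where the three letters
    select the low/high-pass filter along the (x, y, z) axes in that order.
    Being undecimated, each subband has the input's shape and the transform
    is translation-equivariant away from the padded boundary.
    """
    arr = volume.array if isinstance(volume, ImageVolume) else np.asarray(volume, dtype=float)
    lo, hi = _wavelet_filters(FILTER_CONFIG["wavelet.family"])
    if min(arr.shape) < len(lo):
        raise ValueError(
            f"every axis must be at least the filter length ({len(lo)}), got shape {arr.shape}"
        )
    mode = FILTER_CONFIG["boundary"]
    out: dict[str, np.ndarray] = {}
    # array axes are (z, y, x); letter k of the name applies to axis x,y,z
    for name in SUBBAND_NAMES:
        sub = arr.astype(float)
        for letter, axis in zip(name, (2, 1, 0)):
            kern = lo if letter == "L" else hi
            sub = ndimage.correlate1d(sub, kern, axis=axis, mode=mode)
        out[name] = sub
    return out


def log_filter(
    volume: ImageVolume | np.ndarray,
    sigma_mm: float | None = None,
    mode: str = "3D",
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Laplacian-of-Gaussian response at a fixed physical scale.

    ``mode="3D"`` applies the operator volumetrically; ``mode="2D"`` applies
    it independently within each axial (z) slice, blind to through-plane
    variation. Intended for the resampled 1 mm isotropic grid.
    """
    if sigma_mm is None:
        sigma_mm = FILTER_CONFIG["log.sigma_mm"]
    if sigma_mm <= 0:
        raise ValueError("sigma must be > 0")
    arr = volume.array if isinstance(volume, ImageVolume) else np.asarray(volume, dtype=float)
    arr = arr.astype(float)
    bnd = FILTER_CONFIG["boundary"]
    sig = [sigma_mm / s for s in spacing]
    # truncate at 6 sigma: a 4-sigma kernel leaves a ~1e-3 DC residual
    if mode == "3D":
        return ndimage.gaussian_laplace(arr, sigma=sig, mode=bnd, truncate=6.0)
    if mode == "2D":
        out = np.empty_like(arr)
        for z in range(arr.shape[0]):
            out[z] = ndimage.gaussian_laplace(arr[z], sigma=sig[1:], mode=bnd, truncate=6.0)
        return out
    raise ValueError(f"mode must be '2D' or '3D', got {mode!r}")


def filter_bank(
    volume: ImageVolume | np.ndarray, which: set[str] | None = None
) -> dict[str, np.ndarray]:
    """Compute the named filtered variants of a volume.

    Keys follow the feature-name prefixes: ``original``, ``Wv LLL``..
    ``Wv HHH``, ``LoG 3mm 2D``, ``LoG 3mm 3D``. ``which`` restricts
    computation to the listed names (the registry passes only the prefixes it
    needs, so unused filters are skipped).
    """
    arr = volume.array if isinstance(volume, ImageVolume) else np.asarray(volume, dtype=float)
    wanted = None if which is None else set(which)

    def need(name: str) -> bool:
        return wanted is None or name in wanted

    bank: dict[str, np.ndarray] = {}
    if need("original"):
        bank["original"] = arr.astype(float)
    if wanted is None or any(w.startswith("Wv ") for w in wanted):
        for name, sub in wavelet_subbands(arr).items():
            if need(f"Wv {name}"):
                bank[f"Wv {name}"] = sub
    for m in ("2D", "3D"):
        key = f"LoG 3mm {m}"
        if need(key):
            bank[key] = log_filter(arr, mode=m)
    return bank
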