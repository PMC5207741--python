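"""Radiomic feature computation: shape, first-order statistics and texture.

Canonical feature names follow the ``[filter prefix] + family + feature``
scheme used on CT radiomics panels, e.g. ``Wv HLH GLSZM high intensity large
area emphasis`` or ``LoG 3mm 2D skewness``. Shape features are computed once
from the mask and are filter-independent; statistics features come from the
raw filtered intensities inside the mask; texture features (GLCM, GLRLM /
RLGL, GLSZM) are computed on the 25-unit fixed-width binned volume, each
filtered image binned with its own mask-minimum anchor.

Conventions pinned here (and surfaced in the registry metadata):

* GLCM: distance 1, symmetric accumulation, 13 unique 3D directions (or the
  4 in-plane directions, pooled over axial slices, for 2D-filtered images);
  features are computed per direction and averaged.
* GLRLM: maximal runs per direction, averaged over the 13 3D directions.
* GLSZM: zones are 26-connected components of constant gray level,
  normalized by total zone count.
* Kurtosis is Pearson (non-excess): a Gaussian scores 3.
* Surface area comes from a marching-cubes triangulation at the 0.5 level;
  voxel-face counting would systematically inflate it and bias sphericity
  down.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import pdist
from skimage import measure

from .filters import filter_bank
from .io import ImageVolume
from .preprocess import DiscretizationSpec, discretize, resample_isotropic

__all__ = [
    "FeatureVector",
    "shape_features",
    "firstorder_features",
    "glcm_matrix",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "extract_all",
    "extract_cohort",
    "sphericity",
    "compactness2",
    "sphere_disproportion",
    "TABLE2_FB",
    "TABLE2_AIP",
    "TABLE2_ALL",
    "get_registry",
    "DIRECTIONS_3D",
]

# ---------------------------------------------------------------------------
# direction sets

#: the 13 unique 3D offsets at Chebyshev distance 1 (negatives are implied
#: by symmetric accumulation)
DIRECTIONS_3D: list[tuple[int, int, int]] = [
    d for d in product((-1, 0, 1), repeat=3) if d > (0, 0, 0)
]
assert len(DIRECTIONS_3D) == 13

#: in-plane (y, x) offsets for 2D texture on axial slices
DIRECTIONS_2D: list[tuple[int, int]] = [(0, 1), (1, 0), (1, 1), (1, -1)]


# ---------------------------------------------------------------------------
# shape


def sphericity(volume_mm3: float, surface_mm2: float) -> float:
    """pi^(1/3) (6V)^(2/3) / A — 1 for a perfect sphere, <1 otherwise."""
    return float(np.pi ** (1 / 3) * (6 * volume_mm3) ** (2 / 3) / surface_mm2)


def sphere_disproportion(volume_mm3: float, surface_mm2: float) -> float:
    """A / (4 pi R^2) with R the radius of the equal-volume sphere (= 1/sphericity)."""
    r = (3 * volume_mm3 / (4 * np.pi)) ** (1 / 3)
    return float(surface_mm2 / (4 * np.pi * r**2))


def compactness2(volume_mm3: float, surface_mm2: float) -> float:
    """36 pi V^2 / A^3 — 1 for a sphere (= sphericity cubed)."""
    return float(36 * np.pi * volume_mm3**2 / surface_mm2**3)


def _max_axial_diameter(mask: np.ndarray, spacing) -> float:
    """Largest in-slice pairwise distance (mm) over all axial slices."""
    best = 0.0
    sy, sx = spacing[1], spacing[2]
    for z in range(mask.shape[0]):
        pts = np.argwhere(mask[z])
        if len(pts) < 2:
            continue
        phys = pts * np.array([sy, sx])
        if len(phys) > 400:
            # the diameter is attained on the convex hull
            from scipy.spatial import ConvexHull

            try:
                phys = phys[ConvexHull(phys).vertices]
            except Exception:
                pass
        best = max(best, float(pdist(phys).max()))
    return best


def shape_features(mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> dict[str, float]:
    """Volume, axial diameter and surface-derived shape descriptors of a mask."""
    mask = np.asarray(mask).astype(bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("mask is empty")
    voxvol = float(np.prod(spacing))
    out: dict[str, float] = {"volume": n * voxvol}
    out["max_axial_diameter"] = _max_axial_diameter(mask, spacing)
    try:
        # a light Gaussian pre-smooth removes the staircase facets that
        # otherwise inflate the triangulated area by ~8%
        padded = ndimage.gaussian_filter(np.pad(mask.astype(float), 2), 0.7)
        verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
        area = float(measure.mesh_surface_area(verts, faces))
        out["surface_area"] = area
        out["sphericity"] = sphericity(out["volume"], area)
        out["sphere_disproportion"] = sphere_disproportion(out["volume"], area)
        out["compactness2"] = compactness2(out["volume"], area)
    except (RuntimeError, ValueError):
        # e.g. a single-voxel mask has no triangulable isosurface
        for k in ("surface_area", "sphericity", "sphere_disproportion", "compactness2"):
            out[k] = float("nan")
    return out


# ---------------------------------------------------------------------------
# first order


def firstorder_features(values: np.ndarray, voxel_volume: float = 1.0) -> dict[str, float]:
    """Histogram statistics with population (denominator N) moments.

    Skewness is ``m3 / m2^1.5`` and kurtosis the Pearson ``m4 / m2^2``;
    both are NaN for a zero-variance region rather than 0.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("no values supplied")
    mean = x.mean()
    d = x - mean
    m2 = float(np.mean(d**2))
    out = {
        "min": float(x.min()),
        "max": float(x.max()),
        "range": float(x.max() - x.min()),
        "mean": float(mean),
        "variance": m2,
        "total_energy": float(voxel_volume * np.sum(x**2)),
    }
    if m2 > 0:
        out["skewness"] = float(np.mean(d**3) / m2**1.5)
        out["kurtosis"] = float(np.mean(d**4) / m2**2)
    else:
        out["skewness"] = float("nan")
        out["kurtosis"] = float("nan")
    return out


# ---------------------------------------------------------------------------
# GLCM


def _offset_slices(shape, off):
    src, dst = [], []
    for n, o in zip(shape, off):
        src.append(slice(max(0, -o), n - max(0, o)))
        dst.append(slice(max(0, o), n - max(0, -o)))
    return tuple(src), tuple(dst)


def glcm_matrix(binned: np.ndarray, mask: np.ndarray, offset, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence counts for one voxel offset (masked pairs only)."""
    src, dst = _offset_slices(binned.shape, offset)
    a, b = binned[src], binned[dst]
    valid = mask[src] & mask[dst]
    P = np.zeros((n_levels, n_levels))
    np.add.at(P, (a[valid] - 1, b[valid] - 1), 1.0)
    return P + P.T


def _glcm_stats(P: np.ndarray) -> dict[str, float]:
    total = P.sum()
    nan = float("nan")
    keys = ("homogeneity1", "correl1", "infoCorr1", "infoCorr2", "clusShade", "clusProm")
    if total == 0:
        return dict.fromkeys(keys, nan)
    p = P / total
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    out = {"homogeneity1": float(np.sum(p / (1.0 + np.abs(ii - jj))))}
    mx, my = float(i @ px), float(i @ py)
    vx = float(((i - mx) ** 2) @ px)
    vy = float(((i - my) ** 2) @ py)
    if vx > 0 and vy > 0:
        out["correl1"] = float((np.sum(ii * jj * p) - mx * my) / np.sqrt(vx * vy))
    else:
        out["correl1"] = nan

    nz = p > 0
    hxy = float(-np.sum(p[nz] * np.log2(p[nz])))
    pxy = np.outer(px, py)
    nzj = pxy > 0
    hxy1 = float(-np.sum(p[nz & nzj] * np.log2(pxy[nz & nzj])))
    hxy2 = float(-np.sum(pxy[nzj] * np.log2(pxy[nzj])))
    hx = float(-np.sum(px[px > 0] * np.log2(px[px > 0])))
    hy = float(-np.sum(py[py > 0] * np.log2(py[py > 0])))
    denom = max(hx, hy)
    out["infoCorr1"] = float((hxy - hxy1) / denom) if denom > 0 else nan
    out["infoCorr2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    c = ii + jj - mx - my
    out["clusShade"] = float(np.sum(c**3 * p))
    out["clusProm"] = float(np.sum(c**4 * p))
    return out


def glcm_features(binned: np.ndarray, mask: np.ndarray, mode: str = "3D") -> dict[str, float]:
    """Haralick-style GLCM features, averaged over directions.

    In 3D mode co-occurrences are accumulated over the 13 unique distance-1
    offsets; in 2D mode over the 4 in-plane offsets, with each direction's
    matrix pooled across axial slices before the feature is computed.
    """
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    ng = int(binned[mask].max())
    if mode == "3D":
        offsets = [d for d in DIRECTIONS_3D]
    elif mode == "2D":
        offsets = [(0, dy, dx) for dy, dx in DIRECTIONS_2D]
    else:
        raise ValueError(f"mode must be '2D' or '3D', got {mode!r}")
    mats = [glcm_matrix(binned, mask, off, ng) for off in offsets]
    per_dir = [_glcm_stats(P) for P in mats if P.sum() > 0]
    if not per_dir:
        raise ValueError("no co-occurring voxel pairs inside the mask")
    keys = per_dir[0].keys()
    return {k: float(np.mean([d[k] for d in per_dir])) for k in keys}


# ---------------------------------------------------------------------------
# GLRLM


def _runs_for_direction(binned, mask, d):
    """Lengths and gray levels of maximal runs along direction ``d``.

    Voxels on a lattice line through direction ``d`` are grouped by the two
    line invariants, ordered by the projection ``t = p . d``; a gap in ``t``,
    a line change or a gray-level change ends a run.
    """
    coords = np.argwhere(mask)
    if coords.size == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    z, y, x = coords.T
    dz, dy, dx = d
    t = z * dz + y * dy + x * dx
    if dz != 0:
        u = y * dz - z * dy
        v = x * dz - z * dx
    elif dy != 0:
        u = z
        v = x * dy - y * dx
    else:
        u = z
        v = y
    order = np.lexsort((t, v, u))
    u, v, t = u[order], v[order], t[order]
    g = binned[mask][order]
    step = dz * dz + dy * dy + dx * dx
    brk = (np.diff(u) != 0) | (np.diff(v) != 0) | (np.diff(t) != step) | (np.diff(g) != 0)
    bounds = np.concatenate(([0], np.flatnonzero(brk) + 1, [len(g)]))
    lengths = np.diff(bounds)
    levels = g[bounds[:-1]]
    return lengths, levels


def glrlm_features(
    binned: np.ndarray, mask: np.ndarray, directions=None
) -> dict[str, float]:
    """Run-length features; currently low gray level run emphasis (LGLRE).

    LGLRE = (sum over runs of 1/i^2) / (number of runs), averaged over the
    13 unique 3D directions — near 1 when low-bin voxels dominate the runs.
    """
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if directions is None:
        directions = DIRECTIONS_3D
    vals = []
    for d in directions:
        lengths, levels = _runs_for_direction(binned, mask, d)
        vals.append(float(np.mean(1.0 / levels.astype(float) ** 2)))
    return {"low gray level run emphasis": float(np.mean(vals))}


# ---------------------------------------------------------------------------
# GLSZM

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_features(binned: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Size-zone features from 26-connected constant-gray zones.

    LAE = (sum over zones of j^2) / N_z and HILAE = (sum of i^2 j^2) / N_z
    where i is the zone gray level, j its size and N_z the zone count.
    """
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    levels = np.unique(binned[mask])
    lae_num = 0.0
    hilae_num = 0.0
    n_zones = 0
    for g in levels:
        lab, nlab = ndimage.label((binned == g) & mask, structure=_STRUCT_26)
        if nlab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:].astype(float)
        n_zones += nlab
        lae_num += float(np.sum(sizes**2))
        hilae_num += float(g) ** 2 * float(np.sum(sizes**2))
    return {
        "large area emphasis": lae_num / n_zones,
        "high intensity large area emphasis": hilae_num / n_zones,
    }


# ---------------------------------------------------------------------------
# registry and orchestration

_SHAPE_MAP = {
    "Volume": "volume",
    "Max diameter": "max_axial_diameter",
    "Sphericity": "sphericity",
    "Sphere disproportionality": "sphere_disproportion",
    "Compactness2": "compactness2",
}

_STATS_MAP = {
    "min": "min",
    "max": "max",
    "range": "range",
    "mean": "mean",
    "var": "variance",
    "skewness": "skewness",
    "kurtosis": "kurtosis",
    "total energy": "total_energy",
}

_GLCM_FEATURES = {"homogeneity1", "correl1", "infoCorr1", "infoCorr2", "clusShade", "clusProm"}
_FILTER_PREFIXES = (
    ["Wv " + "".join(s) for s in product("LH", repeat=3)]
    + ["LoG 3mm 2D", "LoG 3mm 3D"]
)


@dataclass(frozen=True)
class _Entry:
    name: str
    family: str  # shape | stats | GLCM | GLRLM | GLSZM
    filter_key: str  # 'original', 'Wv LLL', ..., 'LoG 3mm 2D/3D'; '' for shape
    feature: str


def _parse_name(name: str) -> _Entry:
    if name in _SHAPE_MAP:
        return _Entry(name, "shape", "", _SHAPE_MAP[name])
    rest = name
    filter_key = "original"
    for pref in _FILTER_PREFIXES:
        if rest.startswith(pref + " "):
            filter_key = pref
            rest = rest[len(pref) + 1 :]
            break
    if rest.startswith("GLCM "):
        feat = rest[5:]
        if feat not in _GLCM_FEATURES:
            raise ValueError(f"unknown GLCM feature in {name!r}: {feat!r}")
        return _Entry(name, "GLCM", filter_key, feat)
    if rest.startswith("GLSZM "):
        return _Entry(name, "GLSZM", filter_key, rest[6:])
    if rest.startswith("RLGL "):
        return _Entry(name, "GLRLM", filter_key, rest[5:])
    if rest in _STATS_MAP:
        return _Entry(name, "stats", filter_key, _STATS_MAP[rest])
    raise ValueError(f"cannot parse feature name {name!r}")


#: the 21 features analysed per image type (2 conventional + 19 radiomic)
TABLE2_COMMON = [
    "Volume",
    "Max diameter",
    "Sphericity",
    "Sphere disproportionality",
    "Wv LLL max",
    "Wv HHL range",
    "LoG 3mm 2D skewness",
    "LoG 3mm 3D GLCM homogeneity1",
]

TABLE2_FB = TABLE2_COMMON + [
    "Wv HLL max",
    "Wv LLH total energy",
    "Wv LLH mean",
    "Wv LHL skewness",
    "Wv HLL var",
    "Wv HLH min",
    "Wv LHL GLCM correl1",
    "Wv HLH GLCM correl1",
    "Wv LLL GLCM infoCorr2",
    "LoG 3mm 3D GLCM clusProm",
    "Wv HLH GLSZM high intensity large area emphasis",
    "LoG 3mm 2D GLCM clusShade",
    "Wv LLL GLCM infoCorr1",
]

TABLE2_AIP = TABLE2_COMMON + [
    "Compactness2",
    "LoG 3mm 3D skewness",
    "Wv HHL kurtosis",
    "Wv LLH skewness",
    "Wv HLL skewness",
    "LoG 3mm 3D GLCM infoCorr2",
    "GLCM correl1",
    "LoG 3mm 3D GLCM correl1",
    "Wv LLL GLCM clusShade",
    "LoG 3mm 2D GLCM clusProm",
    "Wv HLH RLGL low gray level run emphasis",
    "Wv LHH GLSZM large area emphasis",
    "Wv LHH GLCM correl1",
]

TABLE2_ALL = TABLE2_FB + [n for n in TABLE2_AIP if n not in TABLE2_FB]

_REGISTRIES = {"table2_fb": TABLE2_FB, "table2_aip": TABLE2_AIP, "all": TABLE2_ALL}


def get_registry(name_or_list) -> list[str]:
    """Resolve a registry name (``table2_fb`` / ``table2_aip`` / ``all``) or
    pass through an explicit list of canonical feature names."""
    if isinstance(name_or_list, str):
        try:
            return list(_REGISTRIES[name_or_list])
        except KeyError:
            raise ValueError(
                f"unknown registry {name_or_list!r}; choose from {sorted(_REGISTRIES)}"
            ) from None
    return list(name_or_list)


@dataclass
class FeatureVector:
    """Named feature values for one subject and image type."""

    values: dict[str, float]
    flags: dict[str, str] = field(default_factory=dict)
    image_type: str = ""
    subject_id: str = ""

    def to_series(self) -> pd.Series:
        s = pd.Series(self.values, name=self.subject_id or None)
        s.attrs["image_type"] = self.image_type
        return s


def extract_all(
    volume: ImageVolume,
    mask: np.ndarray,
    registry="all",
    image_type: str = "",
    subject_id: str = "",
    bin_width: float = 25.0,
    resample: bool = True,
) -> FeatureVector:
    """Run the full chain preprocess -> filters -> features for one image.

    Resamples to the 1 mm grid, crops to the mask bounding box with enough
    margin for the filter supports, computes only the filtered variants the
    registry needs, and discretizes each with the same 25-unit bin width
    anchored at its own in-mask minimum. Features that are undefined (e.g.
    correlation on a single gray level) come back NaN with a reason flag.
    """
    names = get_registry(registry)
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"registry naming collision: {dupes}")
    entries = [_parse_name(n) for n in names]

    if resample:
        volume, mask = resample_isotropic(volume, mask)
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("mask is empty after preprocessing")

    # crop to the mask bounding box plus filter-support margin
    margin = 12
    sl = []
    for ax in range(3):
        idx = np.flatnonzero(mask.any(axis=tuple(a for a in range(3) if a != ax)))
        sl.append(slice(max(0, idx[0] - margin), min(mask.shape[ax], idx[-1] + 1 + margin)))
    sub = volume.array[tuple(sl)]
    submask = mask[tuple(sl)]

    needed = {e.filter_key for e in entries if e.family != "shape"}
    bank = filter_bank(sub, which=needed) if needed else {}
    dspec = DiscretizationSpec(bin_width)

    shape_vals = shape_features(mask, volume.spacing) if any(
        e.family == "shape" for e in entries
    ) else {}
    stats_cache: dict[str, dict[str, float]] = {}
    texture_cache: dict[tuple[str, str], dict[str, float]] = {}
    binned_cache: dict[str, np.ndarray] = {}

    def binned_for(key: str) -> np.ndarray:
        if key not in binned_cache:
            binned_cache[key] = discretize(bank[key], submask, dspec)
        return binned_cache[key]

    values: dict[str, float] = {}
    flags: dict[str, str] = {}
    for e in entries:
        if e.family == "shape":
            v = shape_vals[e.feature]
            if not np.isfinite(v):
                flags[e.name] = "surface undefined for degenerate mask"
        elif e.family == "stats":
            if e.filter_key not in stats_cache:
                stats_cache[e.filter_key] = firstorder_features(
                    bank[e.filter_key][submask], volume.voxel_volume
                )
            v = stats_cache[e.filter_key][e.feature]
            if not np.isfinite(v):
                flags[e.name] = "undefined (zero variance)"
        else:
            ck = (e.filter_key, e.family)
            if ck not in texture_cache:
                b = binned_for(e.filter_key)
                if e.family == "GLCM":
                    mode = "2D" if e.filter_key == "LoG 3mm 2D" else "3D"
                    texture_cache[ck] = glcm_features(b, submask, mode=mode)
                elif e.family == "GLRLM":
                    texture_cache[ck] = glrlm_features(b, submask)
                else:
                    texture_cache[ck] = glszm_features(b, submask)
            v = texture_cache[ck][e.feature]
            if not np.isfinite(v):
                flags[e.name] = "undefined (degenerate gray-level distribution)"
        values[e.name] = float(v)

    return FeatureVector(values, flags, image_type=image_type, subject_id=subject_id)


def extract_cohort(
    images: list[tuple[ImageVolume, np.ndarray]],
    registry="all",
    image_type: str = "",
    subject_ids: list[str] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Extract a subjects x features table from a list of (volume, mask) pairs."""
    ids = subject_ids or [f"S{i:03d}" for i in range(len(images))]
    rows = [
        extract_all(vol, msk, registry, image_type=image_type, subject_id=sid, **kwargs).to_series()
        for (vol, msk), sid in zip(images, ids)
    ]
    df = pd.DataFrame(rows)
    df.index = pd.Index(ids, name="subject_id")
    df.attrs["image_type"] = image_type
    return df
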