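"""Synthetic tumor phantoms, FB/AIP motion pairs, test-retest pairs and outcomes.

This module fabricates every input the analysis pipeline needs, with known
ground truth:

* lobulated ellipsoidal tumor phantoms with correlated internal texture on a
  lung-like background (stand-ins for contoured patient CT volumes),
* free-breathing (FB) vs average-intensity-projection (AIP) image pairs,
  where AIP is the voxelwise mean over rigid superior-inferior respiratory
  shifts of the same volume and FB is a single randomly caught phase,
* test-retest scan pairs whose within-subject disagreement (rigid reposition
  plus fresh noise) is dialled by two parameters, emulating a re-imaging
  reproducibility study,
* right-censored survival outcomes for two recurrence endpoints (distant
  metastasis and locoregional recurrence) tied to features through a
  log-linear proportional-hazards link.

All generators are pure functions of their spec, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import CLINICAL_COLUMNS, ImageVolume

__all__ = [
    "PhantomSpec",
    "MotionSpec",
    "OutcomeSpec",
    "generate_tumor_phantom",
    "simulate_fb_aip",
    "generate_test_retest",
    "simulate_outcomes",
    "compute_bed",
]

_AXIS_NAMES = ("z", "y", "x")


@dataclass
class PhantomSpec:
    """Geometry, texture and noise of one synthetic tumor CT volume.

    Defaults emulate an early-stage lung tumor: a ~2 cm lesion of soft-tissue
    density (~30 HU) in aerated lung (~-800 HU), mild lobulation, and
    millimetre-scale correlated texture.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_radii: tuple[float, float, float] = (12.0, 10.0, 11.0)  # mm, (z, y, x)
    lobulation_amplitude: float = 0.15
    texture_correlation_length: float = 3.0  # mm
    texture_sd: float = 40.0  # HU
    background_hu: float = -800.0
    tumor_hu: float = 30.0
    noise_sd: float = 10.0  # HU
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.tumor_radii):
            raise ValueError(f"tumor_radii must be positive, got {self.tumor_radii}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.lobulation_amplitude <= 1:
            raise ValueError("lobulation_amplitude must be in [0, 1]")


@dataclass
class MotionSpec:
    """Rigid sinusoidal superior-inferior respiratory motion.

    ``amplitude`` is the peak-to-peak excursion in mm along z; the tumor is
    displaced by ``amplitude/2 * sin(2*pi*k/n_phases + offset_k)`` at phase k.
    ``trace`` holds optional per-phase offsets (radians); an empty trace means
    an evenly sampled sinusoid.
    """

    amplitude: float = 10.0  # mm, peak-to-peak
    n_phases: int = 10
    trace: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.n_phases < 1:
            raise ValueError("n_phases must be >= 1")
        if self.trace and len(self.trace) != self.n_phases:
            raise ValueError("trace length must equal n_phases")

    def displacements_mm(self) -> np.ndarray:
        """Per-phase superior-inferior displacement in mm."""
        k = np.arange(self.n_phases)
        offsets = np.asarray(self.trace) if self.trace else np.zeros(self.n_phases)
        return 0.5 * self.amplitude * np.sin(2 * np.pi * k / self.n_phases + offsets)


@dataclass
class OutcomeSpec:
    """Survival-outcome generator for a synthetic cohort.

    Event times are exponential with subject hazard
    ``baseline_rate * exp(coefficients . z)`` where ``z`` are the z-scored
    features; censoring is an independent exponential clock plus an
    administrative cutoff at ``max_followup``. Default rates are calibrated so
    a null cohort shows roughly 20% events per endpoint before censoring over
    a ~4-year accrual window, the event fraction typical of recurrence after
    lung SBRT.
    """

    n_subjects: int = 112
    coefficients: dict = field(default_factory=dict)  # {"dm": array, "lrr": array}
    baseline_rate: float = 0.0095  # events / month
    censor_rate: float = 0.03  # / month
    max_followup: float = 48.0  # months
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.max_followup <= 0:
            raise ValueError("max_followup must be > 0")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be > 0")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")


def _correlated_field(shape, spacing, corr_len_mm, rng) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length."""
    white = rng.standard_normal(shape)
    sigma_vox = [max(corr_len_mm / s, 1e-6) for s in spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    sd = smooth.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return smooth / sd


def generate_tumor_phantom(spec: PhantomSpec) -> tuple[ImageVolume, np.ndarray]:
    """Render a lobulated ellipsoidal tumor in lung background.

    The mask is the support of an implicit surface: an ellipsoid whose radius
    is modulated by a smooth random field scaled by ``lobulation_amplitude``.
    Inside the mask the intensity is ``tumor_hu`` plus correlated Gaussian
    texture; Gaussian scanner noise is added everywhere.

    Returns
    -------
    (ImageVolume, ndarray)
        The HU volume and an aligned boolean tumor mask.
    """
    shape = tuple(int(n) for n in spec.grid_shape)
    half_extent = [0.5 * (n - 1) * s for n, s in zip(shape, spec.spacing)]
    for ax, (r, h) in enumerate(zip(spec.tumor_radii, half_extent)):
        # leave a 1-radius-fraction margin for lobulation bumps
        if r * (1 + spec.lobulation_amplitude) >= h:
            raise ValueError(
                f"tumor radius {r} mm (plus lobulation) exceeds the grid half-extent "
                f"{h:.1f} mm along axis {_AXIS_NAMES[ax]}"
            )

    rng = np.random.default_rng(spec.seed)
    coords = np.meshgrid(
        *[(np.arange(n) - (n - 1) / 2) * s for n, s in zip(shape, spec.spacing)],
        indexing="ij",
    )
    rho = np.sqrt(sum((c / r) ** 2 for c, r in zip(coords, spec.tumor_radii)))

    if spec.lobulation_amplitude > 0:
        # lobulation wavelength ~ half the mean radius gives a few broad bumps
        lob_len = float(np.mean(spec.tumor_radii)) / 2.0
        lob = _correlated_field(shape, spec.spacing, lob_len, rng)
        mask = rho <= 1.0 + spec.lobulation_amplitude * lob
    else:
        rng.standard_normal(shape)  # keep the stream layout stable across amplitudes
        mask = rho <= 1.0

    texture = _correlated_field(shape, spec.spacing, spec.texture_correlation_length, rng)
    volume = np.full(shape, spec.background_hu, dtype=float)
    volume[mask] = spec.tumor_hu + spec.texture_sd * texture[mask]
    if spec.noise_sd > 0:
        volume += spec.noise_sd * rng.standard_normal(shape)
    return ImageVolume(volume, spec.spacing), mask


def _shift_z(arr: np.ndarray, shift_mm: float, spacing_z: float) -> np.ndarray:
    return ndimage.shift(
        arr, (shift_mm / spacing_z, 0.0, 0.0), order=1, mode="nearest", prefilter=False
    )


def simulate_fb_aip(
    volume: ImageVolume, mask: np.ndarray, motion: MotionSpec
) -> tuple[tuple[ImageVolume, np.ndarray], tuple[ImageVolume, np.ndarray]]:
    """Derive an FB/AIP image pair from one static volume under rigid motion.

    FB is a single phase snapshot caught at a seed-chosen random phase, the
    way a free-breathing helical scan freezes an arbitrary point of the
    respiratory cycle. AIP is the voxelwise mean over all phase snapshots;
    its mask is the 0.5-threshold of the averaged shifted masks, mimicking a
    contour drawn on the blurred image.
    """
    if volume.array.shape != mask.shape:
        raise ValueError("volume and mask are not aligned")
    shifts = motion.displacements_mm()
    # verify the mask never leaves the grid
    zs = np.flatnonzero(mask.any(axis=(1, 2)))
    if zs.size:
        max_up = shifts.max() / volume.spacing[0]
        max_down = -shifts.min() / volume.spacing[0]
        if zs[-1] + max_up > mask.shape[0] - 1 or zs[0] - max_down < 0:
            raise ValueError("motion amplitude pushes the tumor off the grid along z")

    maskf = mask.astype(float)
    if motion.amplitude == 0:
        fb = (ImageVolume(volume.array.copy(), volume.spacing), mask.copy())
        aip = (ImageVolume(volume.array.copy(), volume.spacing), mask.copy())
        return fb, aip

    phase_imgs = [_shift_z(volume.array, s, volume.spacing[0]) for s in shifts]
    phase_masks = [_shift_z(maskf, s, volume.spacing[0]) for s in shifts]

    rng = np.random.default_rng(motion.seed)
    j = int(rng.integers(motion.n_phases))
    fb_img = ImageVolume(phase_imgs[j], volume.spacing)
    fb_mask = phase_masks[j] >= 0.5

    aip_img = ImageVolume(np.mean(phase_imgs, axis=0), volume.spacing)
    aip_mask = np.mean(phase_masks, axis=0) >= 0.5
    return (fb_img, fb_mask), (aip_img, aip_mask)


def generate_test_retest(
    spec: PhantomSpec,
    n_subjects: int,
    reimage_shift_mm: float = 1.0,
    reimage_noise_sd: float = 5.0,
) -> list[tuple[tuple[ImageVolume, np.ndarray], tuple[ImageVolume, np.ndarray]]]:
    """Simulate a paired re-imaging study of ``n_subjects`` tumors.

    Each subject gets an individual phantom (radii jittered ~10% around
    ``spec``, independent texture). Scan B is scan A rigidly repositioned by
    a random sub-``reimage_shift_mm`` translation with fresh additive noise of
    sd ``reimage_noise_sd`` — so zero perturbation makes the scans identical
    and larger perturbation lowers every feature's test-retest ICC.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2 (ICC is undefined for one subject)")
    if reimage_noise_sd < 0:
        raise ValueError("reimage_noise_sd must be >= 0")
    if reimage_shift_mm < 0:
        raise ValueError("reimage_shift_mm must be >= 0")

    rng = np.random.default_rng(spec.seed)
    pairs = []
    for i in range(n_subjects):
        radii = tuple(r * float(f) for r, f in zip(spec.tumor_radii, rng.lognormal(0.0, 0.1, 3)))
        sub_spec = PhantomSpec(
            grid_shape=spec.grid_shape,
            spacing=spec.spacing,
            tumor_radii=radii,
            lobulation_amplitude=spec.lobulation_amplitude,
            texture_correlation_length=spec.texture_correlation_length,
            texture_sd=spec.texture_sd,
            background_hu=spec.background_hu,
            tumor_hu=spec.tumor_hu,
            noise_sd=spec.noise_sd,
            seed=int(rng.integers(2**31)),
        )
        vol_a, mask_a = generate_tumor_phantom(sub_spec)
        shift = rng.uniform(-reimage_shift_mm, reimage_shift_mm, 3)
        arr_b = ndimage.shift(
            vol_a.array, shift / np.asarray(spec.spacing), order=1, mode="nearest", prefilter=False
        )
        mask_b = (
            ndimage.shift(
                mask_a.astype(float),
                shift / np.asarray(spec.spacing),
                order=1,
                mode="nearest",
                prefilter=False,
            )
            >= 0.5
        )
        if reimage_noise_sd > 0:
            arr_b = arr_b + reimage_noise_sd * rng.standard_normal(arr_b.shape)
        if reimage_shift_mm == 0 and reimage_noise_sd == 0:
            arr_b, mask_b = vol_a.array.copy(), mask_a.copy()
        pairs.append(
            ((vol_a, mask_a), (ImageVolume(arr_b, spec.spacing), mask_b))
        )
    return pairs


def _endpoint_times(z: np.ndarray, beta: np.ndarray, spec: OutcomeSpec, rng) -> tuple[np.ndarray, np.ndarray]:
    hazard = spec.baseline_rate * np.exp(z @ beta)
    t_event = rng.exponential(1.0 / hazard)
    if spec.censor_rate > 0:
        t_censor = rng.exponential(1.0 / spec.censor_rate, size=len(hazard))
    else:
        t_censor = np.full(len(hazard), np.inf)
    t_censor = np.minimum(t_censor, spec.max_followup)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    return np.maximum(time, 1e-3), event


# SBRT schedules (n_fractions, dose_per_fraction Gy) weighted toward the
# modal 3x18 Gy regimen of early-stage lung cohorts
_SCHEDULES = [(3, 18.0), (4, 12.0), (5, 10.0)]
_SCHEDULE_P = [0.6, 0.2, 0.2]


def simulate_outcomes(features: pd.DataFrame, spec: OutcomeSpec) -> pd.DataFrame:
    """Draw a clinical table (DM and LRR endpoints) linked to the features.

    ``spec.coefficients`` maps endpoint name (``"dm"``/``"lrr"``) to a
    per-feature log-hazard weight vector; a missing endpoint carries no
    signal. Features are z-scored internally before entering the hazard, so
    coefficients are per-SD log hazard ratios.
    """
    X = features.to_numpy(dtype=float)
    n, p = X.shape
    if n != spec.n_subjects:
        raise ValueError(f"features have {n} rows but spec.n_subjects={spec.n_subjects}")
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (X - X.mean(axis=0)) / sd

    betas = {}
    for ep in ("dm", "lrr"):
        b = np.asarray(spec.coefficients.get(ep, np.zeros(p)), dtype=float)
        if b.shape != (p,):
            raise ValueError(
                f"coefficient vector for {ep!r} has length {b.size}, expected {p}"
            )
        betas[ep] = b

    rng = np.random.default_rng(spec.seed)
    time_dm, event_dm = _endpoint_times(z, betas["dm"], spec, rng)
    time_lrr, event_lrr = _endpoint_times(z, betas["lrr"], spec, rng)
    sched = rng.choice(len(_SCHEDULES), size=n, p=_SCHEDULE_P)
    n_fx = np.array([_SCHEDULES[s][0] for s in sched])
    dose = np.array([_SCHEDULES[s][1] for s in sched])

    subject_id = (
        list(features.index.astype(str))
        if not isinstance(features.index, pd.RangeIndex)
        else [f"S{i:03d}" for i in range(n)]
    )
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "time_dm": time_dm,
            "event_dm": event_dm,
            "time_lrr": time_lrr,
            "event_lrr": event_lrr,
            "n_fractions": n_fx,
            "dose_per_fraction": dose,
            "bed": compute_bed(n_fx, dose),
        },
        columns=CLINICAL_COLUMNS,
    )


def simulate_radiomic_cohort(
    n_subjects: int = 112,
    n_radiomic: int = 19,
    n_signal: int = 3,
    beta: float = 0.8,
    fb_attenuation: float = 0.4,
    baseline_rate: float = 0.0095,
    censor_rate: float = 0.03,
    max_followup: float = 48.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Feature-table-level cohort: AIP features carry the hazard signal.

    Emulates the study conditions directly in feature space: two 21-column
    panels (19 radiomic + volume and max diameter) for ``n_subjects``.
    ``n_signal`` AIP radiomic features each carry a per-SD log hazard ratio
    ``beta`` for distant metastasis; the corresponding FB features are
    attenuated copies (correlation ``fb_attenuation``) so FB retains a
    diluted version of the prognostic information, the way motion-blur
    contrast differs between image types. All remaining features are
    independent noise; LRR carries no signal. Default rates give ~20%
    DM events over the follow-up window.

    Returns ``(fb_features, aip_features, clinical)``.
    """
    if n_signal > n_radiomic:
        raise ValueError("n_signal cannot exceed n_radiomic")
    rng = np.random.default_rng(seed)
    cols = [f"radiomic_{i:02d}" for i in range(n_radiomic)] + ["Volume", "Max diameter"]
    aip = pd.DataFrame(rng.standard_normal((n_subjects, len(cols))), columns=cols)
    fb = pd.DataFrame(rng.standard_normal((n_subjects, len(cols))), columns=cols)
    sig_cols = cols[:n_signal]
    mix = np.sqrt(max(0.0, 1.0 - fb_attenuation**2))
    fb[sig_cols] = (
        fb_attenuation * aip[sig_cols].to_numpy()
        + mix * rng.standard_normal((n_subjects, n_signal))
    )
    ospec = OutcomeSpec(
        n_subjects=n_subjects,
        coefficients={"dm": np.full(n_signal, beta)},
        baseline_rate=baseline_rate,
        censor_rate=censor_rate,
        max_followup=max_followup,
        seed=int(rng.integers(2**31)),
    )
    clinical = simulate_outcomes(aip[sig_cols], ospec)
    return fb, aip, clinical


def compute_bed(n_fractions, dose_per_fraction, alpha_beta: float = 10.0):
    """Biologically effective dose ``n*d*(1 + d/(alpha/beta))`` in Gy.

    With the tumor-effect ``alpha_beta`` of 10 Gy, the common lung SBRT
    schedules 3x18 Gy and 5x10 Gy give 151.2 and 100 Gy respectively.
    """
    if alpha_beta <= 0:
        raise ValueError("alpha_beta must be > 0")
    n = np.asarray(n_fractions, dtype=float)
    d = np.asarray(dose_per_fraction, dtype=float)
    if np.any(n < 0) or np.any(d < 0):
        raise ValueError("fraction count and dose must be >= 0")
    bed = n * d * (1.0 + d / alpha_beta)
    return float(bed) if bed.ndim == 0 else bed
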