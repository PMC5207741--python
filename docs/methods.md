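# Methods

This note records the models, conventions and numerical choices behind
`recurrad`, and what the synthetic harness can and cannot establish.

## Synthetic data model

**Tumor phantoms.** A tumor is the support of an implicit surface: an
ellipsoid with semi-axes `tumor_radii` (default 12×10×11 mm, a ~2 cm
lesion) whose radius is modulated by a smooth Gaussian random field scaled
by `lobulation_amplitude` (default 0.15, mild lobulation; wavelength half
the mean radius). Inside, intensity is `tumor_hu` (30 HU, soft tissue) plus
a correlated Gaussian texture (SD 40 HU, correlation length 3 mm); outside,
aerated lung at −800 HU; everywhere, additive white noise (SD 10 HU).
Every generator is a pure function of its spec including the seed.

**Respiratory motion and the FB/AIP contrast.** Motion is rigid
superior–inferior translation with a sinusoidal trace — the dominant
respiratory component, and enough to create the blur contrast between image
types. The FB image is one randomly caught phase (a free-breathing helical
scan freezes an arbitrary phase, not end-exhale); the AIP is the voxelwise
mean over `n_phases` (10) snapshots, its mask the 0.5-threshold of the
averaged shifted masks, mimicking a contour drawn on the blurred image.
`amplitude` is peak-to-peak excursion; in the cohort simulator each subject
draws an amplitude uniformly from 2–18 mm, the clinical range of lung tumor
motion. This is the mechanism that makes AIP genuinely more informative in
the synthetic study: per-patient motion shapes AIP morphology but is
invisible to a static snapshot, so any hazard tied to AIP features reaches
FB only in attenuated form.

**Test-retest pairs.** Scan B is scan A rigidly repositioned by a random
sub-`reimage_shift_mm` translation with fresh additive noise
(`reimage_noise_sd`). Zero perturbation gives bit-identical scans (ICC = 1
for every feature); increasing either knob lowers downstream feature ICC,
fine-texture features first. Defaults (1 mm, 5 HU) emulate a ~15-minute
re-imaging interval. Under these conditions roughly a third of the 34-name
panel passes the ICC > 0.8 gate — the same order as the published 286/644.

**Outcomes.** Event times are exponential with hazard
`baseline_rate · exp(βᵀz)` on z-scored features (β in log hazard ratio per
SD), censoring is an independent exponential clock (`censor_rate`) plus an
administrative cutoff at `max_followup`. Defaults — 0.0095/month baseline,
0.03/month censoring, 48 months — give ~20% DM events and a median
follow-up near 20 months. The real cohort's censoring mechanism is
unreported; this simple stand-in is not a reconstruction of it. Dose
schedules are drawn from {3×18, 4×12, 5×10} Gy weighted toward 3×18, and
BED uses α/β = 10 Gy, the only value consistent with 151.2 Gy for 3×18.

## Analysis conventions

**Grid and binning.** Images are resampled to 1×1×1 mm with separable
cubic-spline interpolation (the 3D reading of "bicubic"); masks with
nearest-neighbour so they stay binary. Gray levels are binned at a fixed
25-unit width anchored at the in-mask minimum with half-open intervals —
min-anchoring makes binning invariant to a constant HU offset. Filtered
images are not in HU; they are re-binned with the same width and their own
in-mask anchor, an interpretation recorded here because the original
analysis does not state the order of filtering and discretization.

**Filters.** The wavelet bank is a single-level undecimated (stationary)
transform; the family (coif1) is pinned in `FILTER_CONFIG` — the choice of
orthogonal family is not asserted as the original authors'. Subband letters
map to axes in (x, y, z) order. "LoG 3 mm" is interpreted as Gaussian σ
(not FWHM), also pinned in config. Both filters use symmetric padding;
Gaussian kernels are truncated at 6σ, where a 4σ truncation leaves a ~10⁻³
DC residual in the Laplacian.

**Texture.** GLCM: distance 1, symmetric accumulation over the 13 unique
3D directions (4 in-plane directions pooled across slices for 2D-filtered
images), features computed per direction then averaged (Haralick's
convention); directions with no valid pair inside the mask are excluded
from the average. A single-gray-level region has homogeneity 1, cluster
moments 0, and undefined (NaN, flagged) correlation-family features.
GLRLM runs are maximal per direction, averaged over 13 directions; GLSZM
zones are 26-connected components, normalized by total zone count (the
N_z variant). All three engines are verified exactly (|Δ| < 10⁻¹⁰) against
brute-force pair-enumeration / run-scan / flood-fill oracles.

**Shape.** Surface area comes from a marching-cubes triangulation at the
0.5 level after a light Gaussian pre-smooth (σ = 0.7 voxel) of the binary
mask: raw binary marching cubes produces 45° staircase facets that inflate
the area ~8% and bias digital-sphere sphericity to 0.92; with the smooth it
sits at 0.99–1.01 across radii 8–20 voxels. Voxel-face counting would be
worse still. Max axial diameter is the largest in-slice pairwise distance
in physical mm (convex-hull accelerated), computed on the resampled 1 mm
grid; the native-grid delta is sub-voxel. Kurtosis is Pearson (Gaussian
→ 3), not excess.

**ICC.** One-way random-effects, single-measure — the default of the
standard inter-rater package lineage; it can go negative, and is NaN for
zero total variance. The stability gate is strict (ICC > 0.8).

**PCA selection.** PCA is run on the correlation matrix (standardized
features) since feature units are incommensurate. Components are retained
to 95% cumulative explained variance; for each retained component the
original feature with maximal |Pearson r| to its scores is taken (ties by
canonical name), duplicates collapsed, and the achieved |r| reported
against the 0.99 benchmark. A hard |r| ≥ 0.99 gate is deliberately *not*
applied: on realistic spectra it frequently selects nothing, which cannot
be the rule that produced a 19-feature panel; the published mapping from
"scores correlated by at least 99%" to a concrete picking rule is ambiguous
and this is one defensible reading. Under an exactly degenerate spectrum
(equal eigenvalues) components mix features arbitrarily and the dedup can
return fewer representatives than there are latent blocks.

**Landmark classification.** "Event" if the endpoint occurred by the
landmark t (median observed event time by default), "no event" if followed
event-free beyond t, "excluded" only if censored before t without an event.
The literal published exclusion sentence ("censored *or* did not have an
event before the time point") would empty the comparison group; the reading
implemented is the only self-consistent one.

**Concordance and the Noether test.** Harrell's pairwise CI: a pair is
usable iff the shorter follow-up ended in an event; feature ties count 0.5;
CI > 0.5 means higher value → earlier event. The test of CI = 0.5 uses a
normal approximation with the asymptotic U-statistic variance estimated
from per-subject concordance/discordance proportions (Pencina–D'Agostino
form); the exact estimator used by the original survcomp version is
unstated, so ours is calibration-tested instead: 1000 null replicates
reject at 5% ± 1.5%. Wilcoxon rank-sum p-values are exact for combined
n ≤ 50 without ties, normal-approximated with tie correction otherwise.
BH-FDR is applied per feature family × endpoint × image type.

**Multivariate comparison.** The model family is proportional hazards
throughout — the published analysis never names its model, but CI-based
validation with lasso path selection in a survival setting implies it.
Selection takes the first 5 features to enter the L1 Cox path (100
log-spaced penalties downward from the all-zero penalty; entry order makes
"reduce to 5" deterministic; within-step ties by name; duplicated columns
collapse to one). Fits are unpenalized Cox (tiny ridge 10⁻⁶ for numerical
safety); non-convergent or degenerate splits are flagged, excluded from
summaries and counted, never imputed. "Permutation test with 200 bootstrap
iterations" is implemented as a paired sign-flip permutation of the
per-split CI differences — the published phrase conflates two procedures,
and label-swap respects the pairing induced by shared splits.

## What the synthetic harness shows — and does not

Passing tests establish internal correctness (formula-level equivalence
with oracles, calibration of the tests under their nulls, recovery of
planted effects) and the qualitative mechanism of the FB/AIP contrast.
They do not certify behavior on real CT: phantoms lack scanner-specific
noise spectra, deformable motion, HU calibration drift and contouring
variability, and the simulated censoring is a stand-in. The published
cohort's exact feature panels and CI values require the undeposited patient
images and are out of reach by construction.

A further caveat worth knowing before using the model-comparison layer on a
single cohort: validation CIs across the 100 splits are correlated through
the fixed cohort, so chance feature–outcome associations persist across
splits and the split-paired permutation test can declare model differences
"significant" on pure-noise cohorts far more often than its nominal level.
Null-calibration statements in the tests are therefore asserted on average
over replicate cohorts. This is a property of the comparison procedure
itself, not of this implementation.

## Problem sizes in the shipped tests

Unit tests run on 32³–56³ phantom grids and cohorts of tens of subjects;
the oracle comparisons use 100 random ≤6³ volumes; the end-to-end
planted-signal check runs 20 repetitions of the full 100-split five-model
suite on 112-subject feature-table cohorts; the study-scale image pipeline
(112 subjects, 64³ grids) runs in about 90 seconds on one CPU.
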