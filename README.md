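# recurrad

**Does the type of planning CT change what radiomics can say about recurrence
after lung SBRT?** Early-stage non-small-cell lung cancer patients treated
with stereotactic body radiotherapy are scanned both free-breathing (FB — a
static helical scan that freezes one arbitrary respiratory phase) and with
4D CT, from which the average intensity projection (AIP — the voxelwise mean
over breathing phases) is reconstructed. The two images show the same tumor
differently: the AIP is motion-blurred, and its blur encodes per-patient
respiratory excursion that a static snapshot cannot.

`recurrad` is a tested, reusable implementation of the full comparison
pipeline — radiomic feature extraction, test-retest stability + variance
feature reduction, univariate prognostic analysis for distant metastasis
(DM) and locoregional recurrence (LRR), and a cross-validated five-model
multivariate comparison — exercised end-to-end on synthetic tumor phantoms
and simulated cohorts with known ground truth. It is aimed at researchers
who want to stress-test this class of radiomics analysis, or reuse its
statistical layer on their own imaging cohorts.

## The pipeline

1. **Synthetic inputs** (`phantom_cohort`): lobulated ellipsoidal tumor
   phantoms in lung background (HU), rigid sinusoidal superior–inferior
   motion producing FB/AIP pairs, test-retest scan pairs with controllable
   reproducibility, and right-censored survival outcomes with exponential
   hazard `h_i = h_0 · exp(βᵀ z_i)` on z-scored features. BED arithmetic
   `n·d·(1 + d/(α/β))` with α/β = 10 Gy.
2. **Preprocessing** (`preprocess`): tricubic resampling to 1×1×1 mm and
   fixed-width gray-level binning, `bin = ⌊(x − min_mask)/25 HU⌋ + 1`.
3. **Filters** (`filters`): the 8 subbands of a single-level undecimated 3D
   wavelet transform (coif1), and Laplacian-of-Gaussian at σ = 3 mm in 2D
   (slice-wise) and 3D.
4. **Features** (`features`): shape (volume, max axial diameter, surface
   area from a marching-cubes mesh, sphericity `π^⅓(6V)^⅔/A`, sphere
   disproportion `A/4πR²`, compactness2 `36πV²/A³`), first-order statistics
   (population moments; Pearson kurtosis), and texture — GLCM (distance 1,
   13 directions, Haralick features incl. information correlations and
   cluster shade/prominence), run-length LGLRE, and size-zone LAE/HILAE
   (26-connected zones). 34 canonical panel names across the FB and AIP
   registries (2 conventional + 19 radiomic each).
5. **Feature reduction** (`stability_select`): one-way single-measure ICC
   `(MSB − MSW)/(MSB + MSW)` on test-retest pairs, keep ICC > 0.8; then PCA
   on the standardized stable features, retain components to 95% cumulative
   variance and pick each component's best-correlated original feature.
6. **Univariate** (`univariate`): z-scores; landmark Wilcoxon rank-sum at
   the median event time (censored-before-landmark subjects excluded);
   Harrell's concordance index (CI) with a Noether-type test of CI = 0.5;
   Benjamini–Hochberg FDR; Spearman FB↔AIP cross-correlation (|ρ| > 0.8
   flagged strong).
7. **Multivariate** (`multivariate`): 100 stratified 80/20 splits with
   matched event ratios; lasso Cox path selection to 5 features; Cox fits
   validated by CI; five models (FB/AIP × conventional/radiomic + combined)
   compared by paired sign-flip permutation over the shared splits.

## Worked example

```python
from recurrad.pipeline import paper_defaults, run_all

report = run_all(paper_defaults(), "demo_run")
print(report["model_median_ci"])
```

With the checked-in defaults (112 subjects, 31 test-retest subjects, ~20%
DM events, per-subject respiratory amplitude 2–18 mm, seed 0) this prints

```
{'FB_conv': 0.564, 'FB_rad': 0.545, 'AIP_conv': 0.491,
 'AIP_rad': 0.610, 'COMB_rad': 0.683}
```

i.e. the AIP radiomic model outperforms the FB radiomic model in median
validation concordance (0.610 vs 0.545; paired permutation p ≈ 0.05),
because in this synthetic cohort the hazard is tied to AIP morphology
(volume and cluster shade), which FB images observe only in attenuated
form. 10 of the 34 features pass the ICC > 0.8 stability gate under the
default re-imaging perturbation, and each image type's panel reduces to
2 conventional + 3 PCA-selected radiomic features. `demo_run/` contains the
feature tables, univariate CSVs per endpoint and image type, the per-split
CI table, a log of every threshold applied, and `report.json` validated
against the published schema.

The same stages are scriptable from a shell:

```bash
recurrad simulate --out cohort/ --seed 1 --n-subjects 8
recurrad extract --image cohort/S000_aip.nrrd --mask cohort/S000_aip_mask.nrrd \
                 --registry table2_aip --out features.csv
recurrad run-all --out demo_run --seed 0
```

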