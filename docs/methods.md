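# Methods

## Generative model of the synthetic population

The synthetic cohort emulates a large multi-site healthy adolescent
sample (ages 8–22). For subject *i* (age *a*, sex *s*, site *k*) and
region *j*:

    TICV_i = T0 · (1 + g·(a−8)) · r^[s=male] · exp(η),   η ~ N(0, 0.03²)
    V_ij   = TICV_i · o_k · b_j · (1 + APR_j/100 · (a−8)) · exp(ε),  ε ~ N(0, s_j²)

so the TICV-corrected value `V/TICV` follows a linear-in-age trajectory
anchored at the age-8 fraction `b_j`, scaled by a site offset and
multiplicative log-normal noise. Parameters, units and defaults:

| parameter | meaning | default | rationale |
|---|---|---|---|
| `b_j` (base_fraction) | region's fraction of TICV at age 8 | per preset (0.45 global grey … 0.0025 amygdala) | realistic shares of intracranial volume |
| `APR_j` | annual percent rate of the corrected trajectory, %/yr | presets: −1.9 (posterior cingulate), −0.8 (amygdala), +0.8 (corticospinal), +0.5 (body CC), +0.1 (genu CC); global grey −17/12, global white +9/12 | the published adolescent rates; global presets are set so the 8→20 change is −17 %/+9 % (= 12·APR under the linear model) |
| `s_j` (noise_sd) | log-scale subject SD | 0.05 | ~5 % coefficient of variation is a realistic between-subject spread; the population value is not published, so this is a free parameter of the emulation |
| sites | count / multiplicative offsets | 3 / (0.98, 1.00, 1.02) | a small site effect (~2 % variance share) typical of pooled multi-scanner cohorts |
| TICV | `T0` 1.35 × 10⁶ mm³ (female, age 8), growth 0.4 %/yr, male ratio 1.10, log-noise 0.03 | — | head size grows through adolescence; males run ~10 % larger, an effect the TICV correction removes |
| male fraction | 852/1232 | — | composition of the emulated population cohort |
| `outlier_fraction` | cells replaced by gross outliers | 0.01 | contamination at ±6–8 log-SD models segmentation failures the QC stage must remove |
| n_subjects / ages | 1200, stratified over year bins 8..22 (uniform within bin) | — | stratification guarantees every year bin > 44 subjects deterministically rather than in expectation |

Patient cohorts shift the healthy value down by `d·σ_j(a)·TICV` where
*d* is the requested deficit in population SD units and `σ_j(a)` is the
analytic SD of the corrected value at the patient's exact age
(site-pooled, log-normal moments). Using the closed form rather than an
empirical bin SD keeps the ground truth exact; the difference from the
bin-level SD is negligible at default noise.

**What the generator does not emulate:** realistic anatomy (phantom
ROIs are uniform-density cuboids on a 32³-scale grid), nonlinear
growth, scanner artefacts/contrast, within-site covariance, missing
data, and age-dependent noise. Passing tests therefore demonstrate the
*statistical machinery* — capping, norm construction, curve recovery,
error rates, lesion-mask algebra — not robustness to real segmentation
output.

## Numerical and procedural choices

- **TICV correction** is the proportional ratio `v/TICV`; a
  residual-regression alternative is available behind
  `correct_table(..., method="residual")`.
- **Capping = exclusion, one pass**, computed per (region, age-year)
  cell on corrected values. A removed value becomes NaN (the subject's
  other regions survive). Recomputed statistics may flag further points;
  a single pass using the original cell statistics is the defined
  behaviour. Zero-SD cells remove nothing and warn. Cells need ≥ 3
  observations.
- **Age bins** are `floor(age)`; bin usability requires n ≥ 45
  (configurable). A bin is "usable" on counts alone; a degenerate
  zero-SD cell is warned at build time and rejected at Z-scoring time,
  so noise-free reference tables can still be constructed.
- **APR baseline** is the fitted value at age 8, the youngest
  population age; this makes 12·APR equal the fitted 8→20 percent
  change exactly, and APR invariant to rescaling all volumes.
- **Variance decomposition** uses sequential (type-I) sums of squares
  in the fixed order age, sex, site on the per-class aggregate of
  corrected volumes. Order matters for correlated predictors; the
  convention is stated here prominently because other attributions
  (type-II/III) would give different shares.
- **Testing is one-sided (lower tail)** because the clinical question
  is low volume; a two-sided option exists (`side="two"`).
  **FDR = Benjamini–Hochberg** at α = 0.05 over a single family of all
  tested regions per subject by default; per-tissue families are
  available via `classify_regions(..., families=...)`.
- **Lesion handling** is exact voxel indexing in a common grid (no
  interpolation); grids must share shape and affine. A region with
  lesion voxel coverage ≥ 0.9 (`coverage_max`) is untestable. The
  phantom abstraction (density × voxel volume) covers both modulated
  probability maps and binary masks.
- **EFA** uses scikit-learn's maximum-likelihood factor analysis with
  varimax rotation on standardized scores; factor signs are oriented so
  the dominant loading is positive. Loadings below the 0.3 cut-off are
  zeroed for reporting; each factor's representative measure is its
  max-|loading| measure, ties broken by name order and logged. The
  eigenvalue scree helper informs the factor count; the default of 5 is
  a fixed design choice.
- **Degenerate inputs**: TICV ≤ 0, empty p-vectors, single-age curve
  fits, all-constant comparison groups, missing parcellation labels and
  geometry mismatches raise immediately with the offending item named.

## Evaluation protocols and problem sizes

`normvol.protocols` fixes the reference experiments, all seeded and run
end to end through the public API:

- **Trajectory recovery**: one cohort of n = 1200 (≥ 45 per year bin),
  default noise; OLS curves after capping. At these settings the APR
  sampling SE is ≈ 0.033 %/yr, so recovery within ±0.1 %/yr is a ~3 SE
  check.
- **Specificity**: 600 healthy subjects classified against norms from
  an independent same-generator cohort; the per-subject false "low
  volume" rate is compared to α + 3·√(α(1−α)/n). Test subjects are
  drawn without the gross-outlier contamination, which models
  population-QC failures (removed by capping), not healthy biology.
- **Power**: 200 patients each carrying a 5 SD deficit in the genu of
  the corpus callosum, classified against independent norms; the
  deficit region itself must survive FDR.
- **Oracle equivalences**: BH against the literal min-over-tail
  definition for family sizes 1–12; ROI extraction against a voxel-loop
  re-summation on random 16³ phantoms; lesion monotonicity under nested
  masks.

## Reporting

`run_pipeline` stamps every artifact with a config hash (over all
result-affecting parameters) and the seed; reruns are byte-identical.
Subject reports are Markdown with a PNG deviation panel — Markdown
covers the report contract and keeps artifacts plain-text; an HTML
renderer would be a thin addition.

## Known limitations

- Linear age trajectories only; real development is non-linear at the
  age-range extremes (splines/GAMMs are out of scope).
- No site harmonization: site offsets are simulated and measured (the
  variance stage) but not removed; quantile-regression or site-offset
  estimation is future work.
- Whether capping should operate globally or per age-cell, and on raw
  or corrected volumes, is underdetermined; per-cell on corrected
  values is this package's documented choice. Likewise the exact APR
  estimator (alternatives such as mean year-over-year change are not
  implemented).
- The subject-level label collapses to any-region-flagged; it carries
  no spatial extent or severity grading.
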