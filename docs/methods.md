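# Methods

`neonicmap` implements two connected analyses for prairie pothole
agro-landscapes: a spatial model of neonicotinoid seed-treatment use, and a
statistical pipeline for censored wetland residue panels. This note
documents the models, the conventions chosen where several were defensible,
the synthetic-data generator, and the problem sizes used in the validation
studies.

## 1. Seed-treatment use model (treatment atlas)

Seed-treatment use is not reported directly, so per-pixel expected use is
reconstructed from three inputs:

* a gridded crop-classification map (integer crop codes; metric pixels,
  e.g. 30, 56 or 100 m edge);
* a treatment registry giving, per (crop, active ingredient), the resolved
  application rate *r* = seed loading (g AI/kg seed) × seeding rate
  (kg seed/ha), in g AI/ha, and the treated fraction *f* ∈ [0, 1] of that
  crop's planted area;
* optionally an external total-cropland estimate for percentages.

Each pixel of crop *c* receives the **expected rate** *r(c, a)·f(c, a)* for
AI *a*; per-AI rasters are summed into a total raster. Pixel area is
(resolution in m)²/10 000 ha. Roll-ups:

* treated area = Σ over pixels with positive rate of *f* × pixel area;
* AI mass (kg) = Σ expected rate × pixel area / 1000;
* percent of cropland = 100 × treated area / total cropland.

Conventions, chosen once and used throughout:

* **Expected-value treatment.** The treated fraction enters
  deterministically as a multiplier, never as stochastic pixel selection.
  All aggregates are then exact expectations and runs are reproducible.
* **Quarter-section tiling.** Rates are aggregated to axis-aligned square
  blocks whose pixel count best approximates 65 ha (the quarter-section
  planting unit); at 100-m pixels that is 8×8 = 64 ha. Edge blocks are
  truncated and area-weighted.
* **Rate categories.** Five half-open bins (lower, upper] partition
  (0, 70] g/ha: Low (0–1.25], Low-Medium (1.25–4], Medium (4–10.5],
  Medium-High (10.5–26], High (26–70]. The upper-inclusive convention puts
  a boundary rate such as 4 g/ha in the bin it closes. Rates above
  70 g/ha raise an error rather than being clipped.
* **Merging AIs.** Rates add; the merged per-pixel treated fraction is the
  maximum of the component fractions (a pixel is treated if treated by any
  AI; per-crop fractions refer to the same planted area, so the max is the
  sharpest safe bound).
* **Multiple label rates** for one crop are reduced to their median before
  registry entry; the registry stores one resolved rate per (crop, AI).
* **Reporting.** Internal computation is unrounded; helper formatters give
  3-significant-figure areas and half-up integer percentages.
* Non-cropland (nodata) pixels contribute zero everywhere and are excluded
  from denominators unless an external cropland total is supplied.

Grids are read and written as single-band TIFF or plain-text matrices; the
package assumes a metric grid and performs no reprojection.

## 2. Censored residue pipeline

Samples are long-format rows: (wetland, quarter section, season, crop,
previous-year crop, matrix, AI, measured value, LOQ, recovery). Matrices
are water (ng/L) and sediment (µg/kg wet weight), treated identically up
to units; no cross-matrix conversion is attempted.

* **Censoring** is decided on the raw measurement: a value below its LOQ
  is a non-detect (ND) and contributes **zero** to sums and arithmetic
  means; a value exactly at the LOQ counts as detected. Detects are then
  **recovery-corrected** (divided by the assay's mean fractional
  recovery). Correcting after the censoring decision means the correction
  can never turn an ND into a detect.
* Two water LOQ sets are configured: the reporting set (acetamiprid 0.25,
  imidacloprid 0.55, clothianidin 0.6, thiamethoxam 0.9 ng/L; default)
  and the analytical-methods set at exactly double those values —
  plausibly a detection-limit vs quantification-limit distinction. The
  default is documented rather than resolved.
* **Total neonicotinoid concentration** per sample is the sum of its
  non-censored AI values (additivity motivated by the compounds' shared
  receptor pharmacology); the total always dominates each single AI.
* **Detection frequency** per season: a wetland is detected if any AI is
  detected; a quarter section if any member wetland is. Wetlands missing
  in a season (dry or flooded) drop out of that season's denominator.
  Percentages are rounded half-up to integers.
* **Crop/season summaries** report n, detection %, arithmetic mean and
  maximum per (season, crop) and analyte, grassland included as the
  reference stratum. The default mean averages all sampled wetlands with
  NDs as zero; a detects-only mean is available (`mean_over="detects"`)
  because published summary tables do not pin down the denominator — their
  per-AI means do not exactly sum to the printed totals under either
  convention.

## 3. Mixed model and contrasts

The response is `log(total + δ)` with δ = half the smallest configured LOQ
by default (0.125 ng/L), which keeps ND totals finite while compressing
them well below the smallest quantifiable value. Fixed effects: season,
crop, season×crop, the baseline (pre-seeding spring) log concentration,
and the previous year's crop; references are summer 2012 and grassland.
Random effects, selectable:

* `nested` — intercepts for quarter section and wetland-within-quarter-
  section (one variance each);
* `season_nested` — season-specific intercept variances at both levels
  (the structure of the reported variance table); this is the default
  specification;
* an optional random time slope at the quarter-section level;
* `none` — ordinary least squares (also the degenerate limit: with all
  random variances at zero the fixed estimates equal the closed-form
  regression solution).

Fitting uses restricted maximum likelihood for reported estimates and
plain maximum likelihood for AIC model selection (REML likelihoods are not
comparable across fixed-effect-identical but differently-parameterized
models, and AIC with ML is the conservative common ground). The optimizer
runs with a 1e-8 relative tolerance and up to three optimizer fallbacks
(L-BFGS, BFGS, CG); non-convergence is flagged, never silent, and
non-convergent candidates are excluded from selection with a warning.
AIC ties within 1e-6 break toward fewer parameters.

**Interaction contrasts.** For a crop *c* and season pair (s₁, s₂) the
contrast is the difference of model-implied cell means at common covariate
values, a linear function Lβ of the fixed effects; the Wald statistic
(Lβ)²/(LVL′) is referred to χ²₁. The default family is every season pair
within every crop present; *k* is the number of contrasts actually tested,
and the family-wise level α is maintained with the Dunn-Šidák per-test
level 1 − (1 − α)^(1/k), which always lies between the Bonferroni level
α/k and α. The Wald/χ² reference treats fixed-effect uncertainty as
Gaussian; with hundreds of observations and ≥ 30 quarter sections the
simulated family-wise error is at or below nominal (see §5).

**Mann-Whitney U** (dried vs still-wet wetlands) counts pairs with a > b
plus half the ties; the two-sided p-value is exact for untied samples with
min(n) ≤ 8 and otherwise uses the tie-corrected normal approximation with
continuity correction.

## 4. Synthetic-data generator

The raw study inputs (proprietary land-cover rasters, confidential
treated-percentage data, field measurements) are unavailable, so the
generator produces stand-ins with known ground truth.

**Landscape.** Quarter-section blocks (default 8×8 pixels at 100 m) each
receive one crop drawn from configurable proportions — prairie crops are
planted at the quarter-section scale, so sub-parcel mixing is not
simulated. Defaults mirror the field study's strata: canola 0.40, barley
0.20, wheat 0.18, oat 0.11, grassland 0.11.

**Residue panel.** The default design is the field design: 50 quarter
sections × up to 3 wetlands × 4 seasons (spring, summer, fall 2012,
spring 2013). Per sample the log total is

    log T = m(crop, season) + u_qs + u_wetland + ε,

with independent Gaussian effects (defaults: σ²_qs = 1.0, σ²_wetland =
0.8, σ²_resid = 1.0, matching the order of magnitude of the reported
variance components). T is split across AIs by mixing weights (default
clothianidin-dominant: 0.6/0.3/0.07/0.03 — a qualitative, not inferential,
choice), each AI is reported as an uncorrected measurement (truth ×
recovery) and censored at its LOQ by the pipeline, and fall samples are
dropped with probability 0.41, sized to the observed fall loss (80 of 136
wetlands still sampled). Default cell means follow the observed seasonal
pattern (low pre-seeding, summer peak, fall decline, spring rebound;
grassland near the LOQs). Crop allocation is random by default; a
deterministic largest-remainder option (`stratified_crops`) guarantees
every stratum is represented and is used by the simulation studies, where
a randomly empty reference stratum or interaction cell would make the
model inestimable by design rather than by data.

What the generator does **not** emulate: spatial autocorrelation between
neighbouring quarter sections, hydrological transport, temporal decay
kinetics, per-AI correlation structure beyond the shared total, and
measurement error beyond censoring. Passing tests therefore demonstrate
correctness of the estimators under the stated lognormal nested model, not
robustness to these real-data features.

## 5. Validation studies and problem sizes

Both studies (in `neonicmap.validation`) run generator → model on the
default 50 × 3 × 4 design with stratified crops, using the uncensored
ground-truth log totals as the response so estimator properties are
isolated from censoring, and with the baseline covariate off (a baseline
that shares the crop effect would absorb part of it by construction).

* **Parameter recovery** — 200 replicates with a +2.0 log-unit barley
  effect: mean bias is well under 10% of the truth and 95% Wald CI
  coverage is within Monte-Carlo error of nominal.
* **Family-wise error** — 500 replicates under a global null (all cell
  means equal): the Šidák-corrected full contrast family (30 contrasts)
  rejects in ≤ α of replicates (slightly conservative, as expected for
  positively correlated contrasts) and raw p-values are approximately
  uniform.

These sizes were chosen as the smallest giving useful Monte-Carlo
precision (binomial standard error ≈ 1.5% for coverage at 200 replicates,
≈ 1% for FWER at 500).

## 6. Degenerate inputs and numerical edges

* Rank-deficient fixed designs raise an estimability error naming the
  aliased columns (QR-diagonal detection); a single-quarter-section panel
  raises a degenerate-structure error.
* A constant response yields zero residual variance and zero effect
  estimates (OLS limit).
* Contrasts of a cell with itself return χ² = 0, p = 1; non-estimable
  cells (missing interaction column) raise an error naming the cell.
* Empty seasons/matrices raise empty-group errors rather than returning
  NaNs; negative measurements, non-positive LOQs and out-of-(0, 1]
  recoveries are rejected at panel construction.

## 7. Known limitations

* The atlas assumes one registry rate per (crop, AI) and a metric,
  unprojected grid; acetamiprid mapping is out of scope (its crop-use data
  are not seed-treatment specific).
* Published prairie-wide totals depend on non-deposited rasters and
  confidential treated fractions, so the package reproduces the roll-up
  arithmetic from published category areas, not the rasters themselves.
* The exact denominator convention of the published concentration means is
  unrecoverable; both supported conventions are documented above.
* No spatial autocorrelation or Bayesian variants; variance-component CIs
  are not reported (Wald intervals on variances are unreliable).
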