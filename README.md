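# neonicmap

Neonicotinoid seed-treatment use mapping and censored wetland-residue
analysis for prairie pothole agro-landscapes.

Neonicotinoid insecticides (clothianidin, thiamethoxam, imidacloprid,
acetamiprid) dominate the seed-treatment market on the Canadian Prairies,
yet their use is not publicly reported and their fate in the region's
millions of depressional "pothole" wetlands is poorly monitored. This
package is for environmental scientists and ecotoxicologists who need to
(1) estimate where and how intensively treated seed is planted, and
(2) turn censored wetland concentration measurements into defensible
detection frequencies, summary tables and inference about crop and
seasonal effects.

## What it computes

**Treatment atlas.** From a gridded crop map and a registry of label
rates, the expected application rate of active ingredient (AI) per pixel
is

    rate (g AI/ha) = seed loading (g AI/kg seed) x seeding rate (kg seed/ha)
                     x treated fraction f in [0, 1]

Pixel area is resolution² / 10⁴ ha. Per-AI rasters are summed, aggregated
to ~65-ha quarter-section parcels (the prairie planting unit), binned
into five rate categories over (0, 70] g/ha, and rolled up into treated
area (Σ f × pixel area), AI mass (Σ rate × area / 1000, kg) and percent
of cropland.

**Residue pipeline.** Long-format water (ng/L) or sediment (µg/kg)
samples with per-AI limits of quantification (LOQ): values below the LOQ
are non-detects contributing zero; detects are recovery-corrected
(x / recovery) and summed into the per-sample total neonicotinoid
concentration. Detection frequencies are reported per season at the
wetland or quarter-section level, and per (season, crop) with means and
maxima.

**Exposure models.** A Gaussian linear mixed model of
log(total + δ) with season × crop fixed effects, baseline and
previous-crop covariates, and nested quarter-section / wetland random
intercepts (optionally season-specific variances or a random time
slope), selected by ML-AIC and reported with REML. Season differences
within crops are tested as Wald χ²₁ interaction contrasts with the
family-wise level held at α by the Dunn-Šidák per-test level
1 − (1 − α)^(1/k). A Mann-Whitney U test compares wetlands that dried in
fall against those that stayed wet.

**Synthetic data.** Block-structured crop landscapes and lognormal
censored panels (50 quarter sections × 3 wetlands × 4 seasons by
default, with fall drawdown dropout) with full ground truth, so every
stage is testable without confidential inputs. See `docs/methods.md` for
model details and conventions.

## Worked example

```python
import neonicmap as nm

# --- use mapping on a synthetic 80x80 landscape (100-m pixels) ---------
grid = nm.gen_landscape(nm.LandscapeConfig(shape=(80, 80), seed=42))
registry = nm.TreatmentRegistry([
    nm.RegistryEntry(nm.CROP_CODES["canola"], "canola", "thiamethoxam", 21.0, 0.95),
    nm.RegistryEntry(nm.CROP_CODES["barley"], "barley", "thiamethoxam", 13.0, 0.60),
    nm.RegistryEntry(nm.CROP_CODES["canola"], "canola", "clothianidin", 10.0, 0.40),
])
total = nm.merge_use_rasters(
    [nm.build_use_raster(grid, registry, ai) for ai in registry.ais]
)
s = nm.summarize_use(total, total_cropland_ha=6400.0)
print(round(s.total_treated_area_ha, 1), round(s.total_mass_kg, 2),
      nm.round_half_up(s.percent_of_cropland))
# 3177.6 70.26 50.0
```

3 177.6 ha of the 6 400-ha scene are expected to be planted with treated
seed (50% of cropland), carrying 70.26 kg of active ingredient; canola
parcels (21 × 0.95 + 10 × 0.40 = 23.95 g/ha expected) fall in the
Medium-High category, barley (7.8 g/ha) in Medium.

```python
# --- residue panel and mixed model -------------------------------------
panel, truth = nm.gen_residue_panel(nm.PanelConfig(seed=42))
for season in nm.SEASONS:
    print(season, nm.detection_frequency(panel, season))
# spring2012 (52, 150, 35)
# summer2012 (95, 150, 63)
# fall2012 (11, 90, 12)
# spring2013 (137, 150, 91)

frame = nm.prepare_model_frame(panel)
fit = nm.fit_lmm(frame, nm.LmmSpec(random="nested"))
print(round(fit.params["crop[canola]"], 2), "+/-", round(fit.bse["crop[canola]"], 2))
# 1.88 +/- 0.5
top = max(nm.interaction_contrasts(fit, alpha=0.05), key=lambda c: c.chi2)
print(top.label, round(top.chi2, 2), top.significant)
# canola: fall2012 vs spring2013 360.67 True
```

Each `(numerator, denominator, percent)` triple is the share of sampled
wetlands with at least one AI at or above its LOQ that season — the
simulated pattern (low pre-seeding, summer peak, fall decline, spring
rebound) follows the generator's calibrated defaults. The fitted canola
effect (+1.88 log units vs grassland at the summer reference) and the
dominant fall-vs-spring contrast (χ²₁ = 360.67, significant at the
Šidák-adjusted level for the 15-contrast family) recover the seasonal
structure built into the simulation.

The same stages are available from a shell via the `neonicmap` CLI
(`simulate`, `map-use`, `summarize-residues`, `fit-model`); every run
writes a manifest with inputs, parameters and seed, and identical
config + seed reproduce byte-identical outputs.

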