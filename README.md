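# thermoscope

Heat tolerance of fishes, its acclimation plasticity, and global maps of
warming tolerance.

Ectotherm vulnerability to warming depends on exposure (the thermal extremes
and seasonality of the habitat) and sensitivity (the organism's upper
thermal limit, and how far acclimation can move it). `thermoscope` is an
analysis pipeline for comparative fish thermal-limit data that

1. **harmonises** heterogeneous assay endpoints — ramped CTmax trials and
   fixed-duration LT trials — to a common 1-hour exposure, using the fitted
   slope *b* of heat tolerance against log₁₀ assay duration
   (HT₁ₕ = HT − *b*·log₁₀ *d*), with *b* estimated by a bootstrap that keeps
   one dynamic record per species-by-study;
2. **quantifies exposure** per species from weekly gridded water
   temperatures over its range: the maximum habitat temperature (97.5th
   range percentile of the 30-year mean annual maximum weekly temperature)
   and the thermal variability (range mean of the across-year average
   within-year CV of weekly temperature, on the Kelvin scale);
3. **fits phylogenetic models**: PGLS with Pagel's λ for species-level
   exposure against realm and absolute latitude, and REML linear mixed
   models of record-level heat tolerance with phylogenetic and species
   random intercepts — a latitude model (cubic latitude × acclimation), a
   habitat model (HT ~ MaxHabitatT + Tvar + AccT + AccT:Tvar + AccT²), and
   a realm model adding realm main effects and AccT:Realm contrasts, with
   an orthogonalised quadratic acclimation term throughout (an optional
   seeded MCMC backend returns posterior summaries of the same shape);
4. **derives plasticity metrics**: the acclimation response ratio
   ARR = ∂HT/∂AccT, warming tolerance WT = HT − MaxHabitatT, the times to
   overheating without and with plasticity t₁ = WT/rate,
   t₂ = t₁/(1 − ARR), and the rate-free time gained by plasticity
   t₃ = (1/(1 − ARR) − 1) × 100%;
5. **maps globally**: the realm model evaluated per gridcell at an
   acclimation anchor (the standardised acclimation at which actual
   acclimation coincides with the cell's maximum weekly temperature), with
   an ARR layer from the +1 °C prediction difference, propagated prediction
   SDs, uncertainty masking and freshwater-priority realm combination.

A first-class synthetic-data generator (`thermoscope.simulate`) builds
complete studies — Yule phylogeny, seasonal freshwater/marine temperature
cubes, Brownian latitudinal range masks, and assay records with known
duration slope, ARR structure and variance components — so every stage is
testable by parameter recovery without any downloaded data. Real inputs in
the same formats (CSV records, Newick tree, NetCDF cubes and masks) are
accepted wherever the synthetic ones are.

## Worked example

```python
import thermoscope as ts
from thermoscope.models import ModelId, ModelSpec, build_design, fit_mixed
from thermoscope.plasticity import PlasticityContext, arr_from_fit, time_gained_pct
from thermoscope.simulate import GridSpec, SimulationConfig
from thermoscope.tolerance import estimate_duration_slope, harmonise_records, records_to_frame

config = SimulationConfig(n_species=60, grid=GridSpec(n_lat=14, n_lon=10), years=4)
bundle = ts.make_bundle(config, seed=1)

slope = estimate_duration_slope(bundle.records, n_bootstrap=50, rng_seed=1)
print(f"log10-duration slope: {slope.slope:+.3f} ± {slope.slope_sd:.3f} °C per log10 h")

frame = records_to_frame(harmonise_records(bundle.records, slope))
table = frame.merge(
    bundle.exposure[["species", "max_habitat_temp", "thermal_variability"]],
    on="species",
)
spec = ModelSpec(ModelId.MODEL3)
y, X, design = build_design(table, spec)
fit = fit_mixed(y, X, bundle.tree, table["species"].to_numpy(str), spec, design)
print(f"model 3: n={fit.n_obs} records, {fit.n_species} species; "
      f"R2 marginal={fit.r2_marginal:.2f}, conditional={fit.r2_conditional:.2f}")

tvar = bundle.exposure["thermal_variability"].mean()
for realm in ("marine", "freshwater"):
    arr = arr_from_fit(fit, PlasticityContext(tvar, realm))
    print(f"{realm}: ARR = {arr:.3f}, time gained = {time_gained_pct(arr):.1f}%")
```

prints

```
log10-duration slope: -1.173 ± 0.053 °C per log10 h
model 3: n=240 records, 60 species; R2 marginal=0.40, conditional=0.93
marine: ARR = 0.172, time gained = 20.8%
freshwater: ARR = 0.190, time gained = 23.5%
```

The slope near −1.2 °C per log₁₀ hour is the duration correction applied to
every endpoint; the marginal/conditional R² split shows habitat fixed
effects explaining ~40% of tolerance variation with phylogeny and species
identity raising the explained share above 90%; the ARR values say a degree
of warm acclimation buys roughly 0.17–0.19 °C of heat tolerance here, which
stretches the time until overheating by ~21–24% regardless of the warming
rate. Freshwater species, generated with hotter and more seasonal habitats,
show the larger ARR.

The same stages run from the shell:

```sh
thermoscope simulate --n-species 60 --grid 12 --seed 1 --out bundle/
thermoscope harmonise --in bundle/records.csv --slope-from fit --seed 1 --out harmonised.csv
thermoscope run --out pipeline_out --seed 1       # full pipeline + manifest
```

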