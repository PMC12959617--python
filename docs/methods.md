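# Methods

## Assay harmonisation

Upper thermal limits come from two assay families. Dynamic (CTmax) assays
ramp temperature from a start value at a fixed rate until loss of function;
their realised duration is (endpoint − start)/ramp rate, unless the study
reports the realised duration directly, in which case the reported value is
preferred. Static (LT) assays report the duration outright; LT50 and LT100
endpoints are treated identically, since a single duration correction is
applied to all records regardless of the mortality fraction.

Because tolerated temperature falls roughly linearly with log exposure time
(the thermal-death-time relationship), endpoints are corrected to a 1-hour
reference: HT₁ₕ = HT − b·log₁₀(d/1 h). The slope b is estimated by a
bootstrap that, per replicate, keeps a single dynamic record per
species-by-study group (so studies contributing many ramped trials do not
dominate), pools these with all static records, and fits heat tolerance on
log₁₀ duration with a species random intercept (plus a phylogenetic
intercept when a tree is supplied); the reported slope is the mean over
replicates, its SD the replicate SD. The log base is configurable (log₁₀
default) and is carried inside `DurationSlope` so estimation and
standardisation can never mix bases.

A caution on the bootstrap SD: it measures record-selection variability
only, not the sampling error of the slope estimator. In simulations its
relation to the true estimator error depends strongly on how many dynamic
trials each study contributes, so it should be read as a
sensitivity-to-selection summary, not a confidence interval half-width.
Recovery of a known slope is tested directly instead (±0.1 at 200 species).

Acclimation temperature is centred within species
(AccT_std = AccT − species mean AccT), removing the correlation between
habitat temperature and the acclimation levels laboratories choose. Species
with records at several latitudes are represented, where a single latitude
is needed, by the record at the median distinct latitude (even counts take
the lower of the two middle values, a deterministic documented tie-break).

## Thermal exposure

Weekly water temperatures are held in Kelvin on a rectangular
(year, week, lat, lon) grid — freshwater and sea-surface cubes are separate
inputs. Per gridcell: the annual maximum weekly temperature is averaged
over years (the climatological annual maximum, reported in °C), and the
within-year CV (sample SD/mean of the weekly values, on the Kelvin scale)
is averaged over years. The Kelvin choice matters: CV magnitudes in the
literature for water temperatures (~0.01–0.05, with realm differences of
~0.006) are only consistent with an absolute-scale denominator, and the
source products store Kelvin. A (cell, year) with fewer than half its weeks
observed is dropped from both aggregations; fully missing cells propagate
as missing. Week-53 values are expected to be folded into week 52 upstream
so cubes stay rectangular.

Per species, the maximum habitat temperature is the 97.5th percentile
(linear-interpolation quantile, fixed for bit-reproducibility) of the
climatological-maximum layer over its range cells, and thermal variability
is the unweighted mean of the CV layer over the same cells. Freshwater
species are summarised from the freshwater cube; marine and brackish
species from the sea-surface cube. Range masks are boolean cell sets;
polygon sources are expected to be rasterised by cell-centre containment
before loading.

## Statistical models

**PGLS.** Species-level exposure metrics are regressed on realm (treatment
contrasts against marine, the largest comparison group) and absolute
latitude (quadratic), with residual correlation λC + (1 − λ)I, where C is
the Brownian correlation of the tree (shared root-to-tip path length,
normalised to unit diagonal; non-ultrametric trees trigger a warning). λ is
profiled over [0, 1] by a 21-point grid scan plus bounded refinement, so the
returned optimum is never worse than the grid. Inference uses t statistics
on n − p degrees of freedom. With λ = 0 the estimates are exactly OLS.

**Mixed models.** Record-level heat tolerance is modelled with three fixed
structures: latitude (signed latitude up to cubic, each interacting with
acclimation — the cubic allows hemispheric asymmetry), habitat (maximum
habitat temperature, thermal variability, acclimation, and the
acclimation × variability interaction), and habitat + realm (adding realm
main effects and acclimation × realm contrasts). All include a quadratic
acclimation term orthogonalised against {1, AccT_std} on the fitted sample
and scaled to unit norm; the basis coefficients (a, b, s) are stored with
the fit so predictions and derivatives on new data reuse the identical
basis. Realm contrast columns are built only for levels present in the
fitted sample; predicting an unfitted level is an error. Latitude enters
raw (not orthogonalised) as printed formulas imply; only the acclimation
quadratic is orthogonal.

Random structure: a phylogenetic species intercept with correlation C at
λ = 1 (its magnitude carried by σ²_phylo, the convention of Bayesian
phylogenetic multilevel software), an independent species intercept, and
optionally a population-within-species intercept (species × collection
latitude) for the local-adaptation sensitivity refit. Fitting maximises the
restricted likelihood over log variance components (Nelder–Mead). Each
objective evaluation uses the Woodbury identity: with loadings
B = [Z₁L₁σ₁ … ] the covariance is V = σ²ₑI + BBᵀ and all GLS quantities
reduce to a factorisation of the q × q capacitance matrix
σ²ₑI + BᵀB (q = number of random levels), so a 1 200-observation,
300-species fit takes seconds. Wald 95% intervals are reported; variance
components collapsing to the boundary give a warning, not an error.

The default backend is REML: deterministic, fast, and for Gaussian
responses at these sample sizes its point estimates and intervals agree
closely with full Bayesian fits of the same model. The optional `mcmc`
backend samples the log variance components with an affine-invariant
ensemble sampler against the marginal (fixed-effects-integrated)
likelihood — equivalent to flat priors on the coefficients and on the log
variances within wide bounds — then draws coefficients from their exact
conditional Gaussian per retained sample; it reports posterior means, SDs
and 2.5/97.5% quantiles in the same `PhyloFit` shape, seeded and
reproducible. Defaults: max(8, 2k + 2) walkers, 600 steps, 200 burn-in,
thin 4.

R² follows the variance-partition (marginal/conditional) definition:
marginal = var(Xβ̂)/(var(Xβ̂) + Σσ²_random + σ²ₑ); conditional adds the
random variances to the numerator. For PGLS the λ share of the residual
variance plays the random-effect role.

## Plasticity metrics

ARR is the derivative of predicted heat tolerance with respect to
standardised acclimation temperature: the linear acclimation coefficient,
plus the thermal-variability interaction times the context CV, plus the
realm contrast, plus the analytic derivative of the stored quadratic basis
at the evaluation point (non-zero away from the basis centre; the default
species-level evaluation point is AccT_std = 0). Because the response is
quadratic in acclimation, the ±0.5 °C central difference of predictions
equals this derivative exactly, which the suite uses as an oracle.

Warming tolerance is heat tolerance minus maximum habitat temperature;
negative values are meaningful (habitat maxima already exceed measured
tolerance). Times to overheating are t₁ = WT/rate and t₂ = t₁/(1 − ARR).
The printed form of the t₁ equation in the source literature has the sign
of the numerator reversed relative to its verbal definition ("time until
overheating"); this implementation uses the positive-time convention.
Species or cells already above tolerance get t₁ = t₂ = 0 and an
`already_overheated` flag rather than negative times. The time gained by
plasticity, (1/(1 − ARR) − 1)×100%, is independent of the warming rate —
asserted over a grid in the tests — so the warming rate is required only
for t₁/t₂ and has no default.

## Global prediction

The realm model is evaluated per gridcell with the cell's climatological
maximum and CV as covariates. Since cells are not species, the acclimation
covariate is anchored: an OLS regression of actual acclimation temperature
on species maximum habitat temperature (requiring ≥ 10 species) gives, for
a cell with maximum temperature T, the standardised acclimation
T − (intercept + slope·T) at which actual acclimation would coincide with
T. The ARR layer is the prediction difference at anchor + 1 °C (one-sided,
as the mapping convention prescribes); note this differs from the analytic
derivative by exactly coef(AccT²)/s, the curvature of the quadratic basis —
a deliberate, documented asymmetry. Prediction SDs propagate the
coefficient covariance through each design row; cells above a threshold
(default: the 90th percentile of the SD layer, recorded in metadata) are
masked, carrying no finite derived values. Freshwater and marine layers
are combined with freshwater priority on overlapping cells (coasts,
estuaries), overlap counts reported, and per-cell provenance kept. Cells
whose anchor falls outside the fitted acclimation range are extrapolations;
they are predicted, not masked.

## Synthetic studies

The generator emulates the statistical structure the analysis assumes, not
the geophysics. Temperature cubes are a latitudinal mean gradient (27 °C at
the equator falling by 22 °C at |lat| = 60°), a seasonal cosine whose
amplitude grows poleward (0.5 → 8 K) with hemisphere-opposed phase, realm
offsets (freshwater +3 °C mean; an amplitude increment sized to raise CV by
~0.006), and weekly Gaussian noise (0.3 K), in Kelvin. Noise-free, the
annual maximum is mean + amplitude in closed form. Ranges are contiguous
latitudinal bands (breadth 9°) whose centres evolve by Brownian motion on a
unit-depth Yule tree, so exposure is phylogenetically structured. Records
follow the realm model: basal tolerance = 18 + 0.46·MaxHabitatT + a
λ-scaled (0.9) Brownian deviate (SD 2 °C) + an iid species deviate (SD
1 °C); per record, ARR(ctx)·AccT_std with
ARR = 0.15 + 2.0·CV + {0, +0.06, +0.04} for marine/freshwater/brackish, a
−0.01 °C/°C² quadratic, the duration effect −1.26·log₁₀(d), and residual
noise (SD 0.75 °C). Species get 4 balanced acclimation levels 3 °C apart
around a species mean that tracks habitat maxima (AccT ≈ 5 + 0.75·MaxT,
SD 1.5 — also the anchor-regression truth), two collection sites (band
centre ± 1°) for population structure, and a 70/30 dynamic/static assay mix
whose stored ramp metadata reproduces the simulated duration exactly.
Default scale is 300 species, 4 levels, a 20×20 grid and 10 years — large
enough for interval-based recovery yet desk-fast; tests use smaller worlds
where only contracts, not power, are at stake.

What the generator does not emulate — river networks, coastlines, depth
structure, observation error in the covariates, correlated study effects,
non-Gaussian residuals — bounds what passing tests show: they demonstrate
that the estimators recover the generating parameters under the model's own
assumptions, not that those assumptions hold for any real dataset.

## Numerical choices and limitations

Quantiles are linear-interpolation order statistics throughout. The
capacitance-matrix REML uses an eigenvalue-based PSD square root of C so
tiny negative eigenvalues from accumulated rounding are tolerated; the λ
profile floors eigenvalue weights at 1e−12. Optimiser termination noise
leaves coefficients reproducible to ~1e−4 across row orderings; written
bundles are byte-identical per seed. Degenerate inputs fail loudly:
constant acclimation (no quadratic basis), rank-deficient designs (with the
collinear columns named), empty masks, all-missing ranges, non-positive
Kelvin temperatures, ARR ≥ 1. GeoTIFF I/O is not provided; gridded data
travel as NetCDF (scipy backend) and tables as CSV. PGLS λ is reported for
exposure models only; in the mixed models phylogenetic signal is expressed
through σ²_phylo at λ = 1, so the two families' "λ" values are not directly
comparable.
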