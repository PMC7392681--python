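# Methods

This note documents the models implemented in `tdfagb`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical conventions fixed throughout the package.

## Plot-level biomass

Tree biomass (kg per stem) comes from six published allometric equations
routed by life form, forest type and stem size. Lianas ≥ 2.5 cm DBH always
use the liana equation; palms use the palm equation, which needs only
height — palms below the nominal 10 cm threshold are routed there anyway
and logged, and the linear palm formula is floored at zero for very short
stems. Trees switch equations at DBH = 10 cm with a half-open convention
(small = [2.5, 10), large = [10, ∞)); this equation switch is distinct from
the 7.5 cm *inventory inclusion* threshold of the main subplots. The `DENSI`
symbol appearing in one published formula is read as wood density (`DENS`),
and `LENG`/`TH` are both read as measured total height in metres. The
modified large-tree equation for semi-evergreen forest is implemented
exactly as printed, including its `0.0939/2` term (whether that term is a
log-scale variance correction already embedded in the source is moot here —
the printed formula is the contract).

Equation outputs are treated as kg per individual; plot AGB in Mg ha⁻¹ is
kg/1000 scaled by 10⁴/area(m²). Large stems (DBH ≥ 7.5 cm) aggregate over
the four 400 m² subplots (1600 m²); small stems (2.5–7.5 cm) exist only in
ICM units' nested 80 m² subplot and scale by 10⁴/80. NFI units therefore
have zero small-stem AGB by construction, which is exactly the bias the
small-tree correction removes. Lianas below 7.5 cm count toward the
small-stem pool. Wood density resolves species → genus mean → mean of the
unit's resolved stems; failure at all three levels is a data error naming
the unit.

## Plot corrections

**Small-tree correction.** AGB proxies stand age, so plots are stratified
per forest type into 5 strata at the 10/25/50/75 % linear-interpolation
percentiles of *large-stem* AGB pooled over NFI+ICM units. Using large-stem
AGB (not total) keeps NFI and ICM units comparable under one set of
breakpoints. The factor per (type, stratum) cell is the ratio of sums
f = Σ agb_total / Σ agb_large over the cell's ICM units — a multiplicative
form, robust to low-AGB plots, chosen because small-stem biomass scales
roughly proportionally with stand biomass within a stratum. Empty cells
fall back to the forest-type-wide ratio (logged). f ≥ 1 always: small trees
only add biomass. Correction state is tracked and a second application is
an error.

**Stand-age correction.** Stand growth follows the monotone saturating
chronosequence AGB(t) = A(1 − e^(−rt)), one curve for the deciduous +
semi-deciduous group and one for the semi-evergreen forest. The form is an
explicit design choice: monotone, saturating, analytically invertible,
g(0) = 0. In the synthetic workflow (A, r) are refit to noisy
chronosequence observations by nonlinear least squares. A plot measured in
year y with AGB x is corrected to the 2015 baseline as
g(g⁻¹(x) + (2015 − y)); growth-only by construction. Plots at or above 99 %
of the asymptote are treated as mature and pass through unchanged (the
inverse diverges there, and old-growth stands are near equilibrium).

The small-tree correction runs first, then the age correction, because the
chronosequence describes *total* AGB; the composed correction never
decreases AGB when f ≥ 1 and Δt ≥ 0.

## SAR predictor stack

Processing order: DN → γ° (dB) via γ° = 10·log₁₀(DN²) − 83.0 (DN = 0 is
no-data, negative DN an error) → 3×3 Lee filter on the dB image →
linearize for NDBI → min–max quantization for textures. The Lee filter uses
the additive-noise local-statistics form on dB imagery
(out = mean + max(0, 1 − σ_n²/σ_local²)·(center − mean)) with a noise SD
parameter in dB; whether the original analysis despeckled in dB or linear
power is not knowable from the source, and the dB choice pairs naturally
with the additive approximation. NDBI is computed on linear power by
default so it is bounded in [−1, 1] (a dB-scale option exists for
comparison).

Textures are second-order Haralick measures (hom, cont, dis, ent, asm,
mean, var, cor) from per-pixel gray-level co-occurrence matrices: 3×3
window, 1-pixel shift, symmetric and normalized matrices, 32 gray levels by
per-band min–max scaling, measures averaged over the four directions 0°,
45°, 90°, 135°. Three bands (HH, HV, NDBI) × 8 measures = 24 texture
layers; with the two polarizations and NDBI themselves plus CWD the full
predictor set has 28 columns. Correlation of a constant window (zero
marginal variance) is defined as 0. Edge pixels use the clipped window;
directions with no admissible pairs are dropped from the average. The
windowed kernel is numba-compiled; the test suite pins it to an exhaustive
pair-enumeration oracle and to an independent library implementation on
whole windows.

Plot features are the mean of each layer over a 1-ha circular footprint
(radius 56.42 m) on the 25 m grid — the imagery grain is matched to the
field sampling unit. Units with centroids off-raster are dropped (logged);
edge footprints average the available pixels and record their coverage.

## Climate water deficit

Stations lacking any of the 12 monthly values are removed. Monthly
precipitation and temperature are interpolated by ordinary kriging with an
exponential variogram γ(h) = sill·(1 − e^(−3h/range)) fitted by weighted
least squares to the binned empirical semivariogram (weights = pair
counts). The nugget is fixed at zero so the interpolator honours station
values exactly (verified to 10⁻⁶); duplicate station coordinates are
averaged. Predictions use the dual kriging form (one solve per month, then
a matrix–vector product over grid pixels).

PET follows Priestley–Taylor, α = 1.26, with the slope of the saturation
vapour-pressure curve from temperature, psychrometric constant 0.0665
kPa °C⁻¹, latent heat λ = 2.501 − 0.002361·T MJ kg⁻¹, and net radiation
taken as a fixed clear-sky fraction (0.5) of the extraterrestrial radiation
computed from standard solar-geometry/day-length formulas for the site
latitude and mid-month day. Using extraterrestrial-derived radiation
(rather than measured net radiation) is a deliberate, flagged choice — the
fraction folds atmospheric transmissivity and net longwave loss into one
constant, adequate for a dry-season water-deficit index. Latitudes beyond
the polar circles are unsupported.

CWD = Σᵢ min(0, Pᵢ − ETᵢ) is summed over all 12 months by default — wet
months contribute zero deficit, so this equals a dry-season-window sum
whenever deficits are confined to the dry season; a month-subset option
exists. CWD ≤ 0 everywhere, more negative = drier.

## LiDAR two-stage upscaling

Stage 1 regresses √AGB on plot-mean LiDAR canopy metrics, searching all
predictor subsets up to size 5 exhaustively and selecting by adjusted R²
(ties break toward the smaller subset, then lexicographic metric order;
ill-conditioned designs are skipped). The square-root transform
linearizes the AGB–structure relation. Validation is leave-one-out with the
selected subset held fixed and per-fold refits; predictions back-transform
by squaring with the linear predictor floored at zero. No
retransformation-bias correction is applied by default; Duan's smearing
estimate is available as an option for sensitivity analysis.

Stage 2 tiles the LiDAR-covered area with non-overlapping 1-ha circular
plots on a regular grid of spacing 2r (plots whose footprint is not fully
covered are skipped) and predicts each plot's AGB from footprint-mean
metrics. These "LiDAR plots" can then train the mapping model alone or
together with the field plots.

## Mapping and validation

The calibration/validation split is stratified over (forest type × AGB
stratum) cells with the global calibration count fixed at ⌊0.7·n⌋;
validation quotas are allocated across cells by largest remainder, which is
what makes the printed split sizes exact (152/66 from 218; 200/87 from
287) — simple per-cell rounding cannot guarantee them. Single-unit cells go
to calibration.

The mapping model is a 500-tree random forest. The number of candidate
predictors per split is tuned over {⌊p/3⌋ − 4, −2, 0, +2, +4} (clipped to
[1, p]) by out-of-bag R². Per-tree predictions stay accessible: the map is
the ensemble mean and the uncertainty surface is the coefficient of
variation over trees (SD/mean), reported as no-data where the mean is below
ε = 1 Mg ha⁻¹ (configurable) to avoid unstable ratios. Three training
approaches — field plots, LiDAR plots, their unweighted union — are always
scored on the same held-out field validation plots, with a hard leakage
check on unit ids.

Validation statistics: errors are predicted − observed; R² is the squared
Pearson correlation by default (a 1 − SSE/SST option exists — the two
differ under systematic bias); SD of error uses the population denominator
so RMSE² = bias² + SD² holds exactly; %RMSE = 100·RMSE/mean(observed).
Moran's I uses inverse-distance, row-standardized weights with no distance
cutoff; the p-value comes from the normal approximation under the
randomization assumption (its empirical size at α = 0.05 is verified at
0.03–0.08 over 1000 null simulations), with a seeded permutation option.
The stratified error profile uses bins 0–50, 50–100, 100–150, 150–200,
> 200 Mg ha⁻¹ with t-based 95 % CIs per bin.

## The synthetic study system

The generator realises, from one seed, everything the analysis consumes.
What it emulates, with defaults:

| parameter | default | why |
|---|---|---|
| landscape grid | 400 × 400 px at 25 m (10 × 10 km) | one scaled-down study site; texture/kriging cost stays desk-scale |
| forest-type bands | 3 vertical bands, drier west → wetter east | the regional moisture gradient separating the three forest types |
| stand age | smooth random field + eastward gradient, rank-mapped to U(2, 80) yr | secondary-forest mosaic; couples age (hence AGB) to moisture so CWD is a genuine predictor |
| chronosequences | deciduous group A = 200 Mg ha⁻¹, r = 0.06 yr⁻¹; semi-evergreen A = 300, r = 0.05 | asymptotes bracket observed dry-forest AGB (up to ~300 Mg ha⁻¹); no parametric curves are published, so these are scenario choices, not estimates |
| small-stem AGB share | f(age) = 0.05 + 0.40·e^(−age/20) | ~0.4 in young stands declining to 0.05 at maturity, matching the known 15–40 % (mature) to ~80 % (young) range for sub-10 cm stems once restricted to < 7.5 cm |
| unit counts | 232 NFI (40/96/96 per type) + 80 ICM; 14 + 11 deforested | reproduces the inventory's printed counts (287 retained = 218 + 69) and the deciduous type's ~quarter sampling intensity |
| measurement years | NFI uniform 2009–2014; ICM 2015 | the temporal-mismatch condition the age correction addresses |
| microsite factor | lognormal, CV = 0.10 per unit | the 1-ha stand deviates from the landscape age–AGB pattern its pixel follows (plot/pixel mismatch). The magnitude is calibrated so the stage-1 LiDAR model sits in the reported high-accuracy regime (mean LOOCV R² ≈ 0.85) |
| backscatter | γ° = floor + gain·(1 − e^(−AGB/150)); HH floor −11 dB gain 4, HV floor −20 dB gain 8 | L-band saturation near 150 Mg ha⁻¹; HV carries more biomass sensitivity than HH |
| speckle | multiplicative gamma, 9 looks | multi-looked mosaic products |
| climate | seasonal P/T profiles with a west–east gradient; 70 stations, 10 with incomplete records | exercises the completeness filter and kriging; dry season November–April |
| LiDAR coverage | 0.9 % of the extent; one 250 m-tall transect per band ("spanning") or transects confined to the oldest semi-evergreen stands ("high_agb") | far-below-1 % coverage; the high-AGB placement reproduces the distribution-shift condition that breaks the LiDAR-plots approach |
| LiDAR metrics | ordered height percentiles, mean, variance, cover as noisy (3 %) monotone transforms of canopy state | plot-scale metrics strongly correlated with structure; point clouds are not simulated |

Tree lists are realised by sampling stems from truncated exponential size
distributions (heights from a deterministic height–diameter curve with
lognormal noise, densities clipped normal, a few percent lianas and palms)
and closing each pool with one bisection-solved stem so the plot total
lands on its AGB target within 1 % and the small-stem share within 0.02.
Simulated digital numbers are kept as float64 so the DN ↔ γ° round trip is
exact to 10⁻⁶ dB; integer quantization would inject rounding noise into a
primitive the tests rely on. All randomness flows through one seeded
generator and its spawned children; no global state.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: topographic and radiometric SAR artifacts
beyond speckle, spatially correlated speckle, geolocation error, floristic
realism (species labels are arbitrary), cloud/no-data masks, mortality or
disturbance between measurement and baseline (the age correction is
growth-only, so a real landscape with disturbance would violate its
assumption), and LiDAR point-cloud processing. Results on synthetic
landscapes show the pipeline's internal correctness and the *direction* of
the studied effects (corrections reduce error; textures + CWD mitigate
saturation; range-restricted LiDAR plots inflate bias), not field-accuracy
levels.

## Problem sizes and runtime choices

The default scenario uses one 400 × 400 landscape; the saturation scenario
adds denser sampling (520 field units). The pipeline-recovery study runs
10 seeds of the saturation scenario; Moran's I calibration uses 1000 null
simulations at n = 100. These sizes keep a full test run and the
acceptance script in the tens-of-minutes range on a single CPU while
leaving every statistical check well-powered.

## Known limitations

- The stratified split guarantees the global calibration count exactly but
  only approximate within-cell proportions (largest remainder).
- Kriging assumes second-order stationarity with one isotropic exponential
  variogram per month; no elevation covariates or lapse rates.
- The OOB tuning grid for the forest is coarse by design; the OOB R² of
  small training sets is noisy, and ties resolve to the smaller
  predictors-per-split value.
- Best-subset search is exhaustive and therefore capped at subsets of 5
  predictors.
- `predict_map` materialises per-tree predictions; for very large rasters
  memory scales with trees × pixels per block.
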