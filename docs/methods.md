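# Methods

## Headspace equilibration

A water sample of volume `V_w` sealed under a headspace `V_h` at total
pressure `P` partitions its dissolved CH₄ until the aqueous and
gas-phase concentrations satisfy `C_aq = H_cc · C_g`. The original
aqueous load is recovered by mole bookkeeping over both phases:

```
n_total = Δx · P/(R·T) · (V_h + H_cc · V_w),   Δx = (c_eq − c_t0) · 10⁻⁶
C_aq,original = n_total · M_CH4 / V_w
```

with `Δx` the background-corrected headspace mole fraction. The
dimensionless constant is extrapolated from a compiled Henry solubility
by the van't Hoff relation `Hcp(T) = Hcp⁰ · exp[B(1/T − 1/298.15)]` and
`H_cc = Hcp·R·T`; with the default `Hcp⁰ = 1.4×10⁻⁵ mol m⁻³ Pa⁻¹` and
`B = 1900 K` this gives `H_cc ≈ 0.057` at 273 K. The extrapolation is
restricted to 260–320 K. Both constants are config values, so an
alternative compilation is a config edit. Assumptions: ideal gas, 1 atm
total pressure (vial over-pressurisation for storage does not enter the
equilibration balance), no salinity/activity correction — appropriate
for dilute glacial meltwater.

Units: headspace readings are ppm by volume; aqueous results are
mg l⁻¹ (mass ppm in water). A headspace reading below background by
more than 0.05 ppm (config) raises a data-quality error rather than
being clipped; smaller negatives are treated as instrument noise.

## Incubation and chamber kinetics

All rates are OLS slopes of concentration on time; a two-point series
degrades to the finite difference with an undefined standard error.
Fits with R² < 0.7 (config) are flagged, not rejected. The slope is
invariant to constant concentration offsets, and both converters are
linear in the slope.

* Slurry vials: blank-corrected slope (ppm h⁻¹) × ideal-gas headspace
  inventory at the incubation temperature → mol h⁻¹, normalised by dry
  sediment mass → fmol g⁻¹ h⁻¹. The dissolved slurry phase is excluded
  by default (headspace gas is what the GC sees); a flag adds it via
  `H_cc`. Rates are reported per hour with a ×24 per-day convenience.
* Static chambers: slope (ppm min⁻¹) × chamber height (the V/A ratio) ×
  molar gas density → µmol m⁻² day⁻¹, positive upward. Deployments are
  validated against the 45-minute window; only the linear model is
  implemented (no exponential/HMR variants).

## Rayleigh isotope systematics

Forward model, closed-form inversion for α, and inversion for the
fraction remaining `f` are exact algebraic rearrangements of the
closed-system relation (README). `fit_alpha_series` regresses
`ln((δ_t+1000)/(δ_i+1000))` on `ln f` **through the origin** — the form
the model implies, since `f = 1` forces `δ_t = δ_i` — and returns
`α = 1/(m+1)` with a delta-method standard error; a point-wise α
average is available for comparison. Degenerate inputs: `f = 1`
carries no information (error if all points are there); `α = 1` with an
enriched residual is flagged as inconsistent; inverted `f > 1` is
returned with a warning, not clipped.

Mixing between a microbial and a geogenic end member is
concentration-weighted in absolute-ratio space (standards
`R_VPDB = 0.011180`, `R_VSMOW = 1.5576×10⁻⁴`, config): deltas are
converted to ratios, weighted by `fraction × concentration`, and
converted back. Weighting by total CH₄ rather than by the light
isotopologue alone overstates the heavy-isotope weight by O(R) ≈ 1 %
of the delta difference — negligible against field scatter.

### Source classification

Fields are config polygons in (δ¹³C, δD) space; defaults are the
literature ranges for biogenic methane (δ¹³C −110 to −50 ‰, δD −531 to
−170 ‰) and geogenic/geothermal methane (δ¹³C −50 to −20 ‰, δD −200 to
0 ‰). A sample inside exactly one polygon takes that label (edge points
count as inside; a point inside two overlapping polygons is an error
surfaced to the caller). Outside both, the sample is `mixed` if within
10 ‰ (Euclidean in delta space, config) of the segment joining the two
field centroids, and `oxidation_affected` if it is enriched in both
systems relative to the microbial centroid, lies beyond the geogenic
field's enriched bounds, and falls within 30 ‰ (config) of the Rayleigh
trajectory anchored at the microbial centroid with the configured
(α_C, α_D) = (1.019, 1.197). Everything else is `indeterminate`.

Because field samples have unknown `f`, classification uses trajectory
*geometry* only — no `f` inversion. The Euclidean delta-space metric
treats 1 ‰ of δ¹³C and 1 ‰ of δD as equivalent; with the default steep
trajectory (near-start slope ≈ 6.3 ‰/‰) the distance is dominated by
the δ¹³C mismatch, which is the discriminating axis. Labels for points
between the mixing band and the trajectory are one defensible
formalisation of a visual argument, and intermediate-point labels
should not be over-interpreted.

## Catchment budget

Export = `Q × C` (m³ s⁻¹ × mg l⁻¹ → t day⁻¹); production capacity =
export / glaciated area in mmol m⁻² day⁻¹; evasion fraction =
`1 − C_down/C_up` (a gaining stream yields a negative fraction with a
logged inconsistency); evasive flux = export × fraction; stream-area
evasion = evasive / (reach length × width) in mol m⁻² day⁻¹. Defaults:
78 km² glaciated area, 4 km × 20 m reach, molar mass 16.04 g mol⁻¹.
Scenario concentrations may be supplied directly or aggregated as the
unweighted mean of per-(year, phase) group means; headline evasion
fractions are accepted as direct scenario inputs, with sample-level
fractions computed alongside when upstream/downstream means exist.
Every `FluxResult` cross-checks its mass and molar forms on
construction (10⁻⁹ relative). All values carry full precision
internally; rounding is a display concern — note that chaining from a
1-significant-figure export value (as terse summaries often do) can
shift the downstream per-area numbers by ~10 %. The mass balance
assumes minimal dilution and no in-stream methanotrophy along the
reach; no k₆₀₀ gas-transfer modelling and no annual hydrograph
integration are attempted.

## Field summaries

Samples are grouped by site class × campaign year × melt-season phase.
Phase comes from day-of-year breakpoints: DOY ≤ 128 `pre_upwelling`,
128 < DOY < 185 `early_post`, DOY ≥ 185 `late_post`; breakpoints are
per-year config (documented values exist only for the 2014 season;
other years reuse them by default). Group statistics are unweighted
arithmetic mean, min/max range and per-variable non-missing counts, so
a sample without isotopes still counts toward the concentration `n`.
Missing values are empty CSV fields, never sentinels.

## Synthetic data generator

The generator encodes the study conditions and known ground truth so
every estimator can be validated as an inverse pair:

* **Campaign**: concentrations are log-normal around the configured
  site-phase mean (arithmetic-mean parameterisation; field ranges are
  strongly right-skewed, e.g. 0.80–18.14 mg l⁻¹ around a mean of 8.17),
  with geometric-σ dispersion plus relative measurement noise. Isotopes
  are end-member mixing at the site's microbial fraction, then Rayleigh
  enrichment at the site's `f`, plus Gaussian ‰ noise.
* **Incubations**: 10 g fresh (8 g dry — a 0.8 dry fraction typical of
  coarse glacial sediment; the dry mass is this package's choice) in
  100 ml vials with 20 ml slurry water and 80 ml headspace at 15 °C.
  Anoxic production series rise linearly at the configured rate
  (default 1.15×10⁷ fmol g⁻¹ h⁻¹) from ambient CH₄, sampled weekly
  over 49 days. Oxic consumption from a 150 ppm amended headspace is
  first-order — the simplest closed-vessel kinetics consistent with the
  Rayleigh formalism — with the initial slope matching the configured
  rate (default −9.6×10⁹ fmol g⁻¹ h⁻¹). Two oxic sampling presets
  exist: a *rate assay* over the first 4 % of consumption, where the
  linear estimator's truncation bias against first-order decay is ~2 %,
  and an *isotope assay* sampled at f = 0.9 → 0.2 for α fitting, with
  residual-pool isotopes following the Rayleigh model at each
  timepoint's `f = C(t)/C(0)`. Concentration noise is parameterised as
  a fraction of the noiseless signal range (default 2 %), isotope noise
  in ‰ (default 0.5 ‰ for the isotope preset).
* **Chambers**: linear ppm drift matching a true areal flux through the
  V/A relation (default 15 cm × 10 cm chambers, ≤ 45 min).

Every generator is deterministic under its single integer seed and
emits a ground-truth key with seed and config hash. What the generators
do **not** emulate: temporal autocorrelation within a site, discharge
variability, substrate limitation or temperature response of the
microbial rates, open-system isotope effects, and analytical drift —
so passing recovery tests demonstrate estimator correctness under the
stated noise model, not robustness to every field pathology.

## Numerical choices and problem sizes

Recovery experiments use 200 replicates per condition with 8 timepoints
per series — large enough for stable medians at negligible cost. The
Rayleigh round-trip is verified to 10 significant figures over
α ∈ [1.001, 1.5], f ∈ [0.01, 0.99], δᵢ ∈ [−110, 0]. Classifier
trajectory distance uses a 400-point geometric `f` grid down to 10⁻⁴.
Polygon containment treats boundaries as inside; summary groups are
emitted in sorted group order so outputs are permutation-invariant.
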