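# Methods

This note records the model structure, the parameter choices that matter,
what the synthetic data do and do not emulate, and the numerical decisions a
maintainer would want to know. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic environmental regimes

The generator (`troutsim.environment`) emulates rain-dominated Oregon Coast
Range hydrology in 365-day water years (Oct 1–Sep 30; Feb 29 dropped so
resampled year blocks are equal length and the storm season never straddles
a block boundary).

* **Temperature**: a sinusoid between the preset's winter minimum and summer
  maximum (trough late January, peak ~Aug 1, period 365.25 d) plus Gaussian
  daily noise (SD 0.3 °C). Defaults span 6–12 °C.
* **Flow**: a smooth seasonal baseflow curve — winter baseflow
  `winter_baseflow_ratio` (default 6×) times the summer level, skewed
  (exponent 1.6 on the seasonal weight) to produce an extended late-summer
  low-flow period — modulated in log space by storm pulses and small daily
  noise. Storms arrive by per-day Bernoulli thinning (expected 12 per Oct–Mar
  season), with lognormal peak sizes scaled by the preset's winter flow CV
  and ~3-day exponential recessions. All stochastic flow structure is scaled
  by `storm_amplitude`, so amplitude 0 returns the deterministic baseflow
  curve exactly — a useful identity for testing.
* **Turbidity**: `coupling × max(flow − baseflow, 0)` — positive, zero in
  quiet periods, strongly rank-correlated with flow.

The four presets (gus, pothole, rock, um) differ only in the *directions*
of their contrasts (deepest pools and most variable winter flow in "gus",
strongest turbidity coupling in "pothole", largest and most summer-variable
flow in "rock", coldest and smallest in "um"). They are synthetic streams:
no preset value is fitted to field data, so absolute response magnitudes in
any downstream table are properties of these synthetic conditions only.
What passing tests show is that the *mechanisms* (phenology responding to
warming, adult biomass responding to baseflow, restoration arithmetic of the
scenario engine) operate as described — not that any field-scale magnitude
is reproduced.

Reach geometries alternate pool-like and riffle-like cells; hydraulic-rating
exponents are drawn from 0.35–0.45 (classic at-a-station hydraulic-geometry
range); ~20 % of cells carry spawning gravel; distance-to-cover is
exponential (mean 3 m, clipped 0.5–15 m). Reference hydraulics are anchored
at the summer baseflow via continuity (`Q = v·d·w`).

## Scenario engine

All rates are fixed by the study design: +0.37 °C harvest pulse with
0.037 °C/yr recovery; +45 % summer flows ramping to baseline at post-harvest
year 20; +20 % storm-day yield above the 2-SD annual threshold; +0.06 °C/yr
warming; −0.25 and −0.49 %-points/yr fall and winter flow declines. Three
points were genuinely open and were resolved as follows:

* **Temperature recovery indexing.** Fifteen elevated years with restoration
  in post-harvest year 16 requires the declining offsets to run
  `0.37 − 0.037·(y − 6)` for years 6–15 (so the last elevated year, 15,
  carries +0.037 and year 16 is exactly 0). With harvests at analysis years
  1 and 41 this restores baseline at years 16 and 56.
* **Summer-flow recovery.** A constant −2.25 %/yr would leave +11.25 % at
  the stated recovery year; the implementation honors the recovery year with
  a linear ramp (3 %-points/yr across post-harvest years 6–19, exactly 1.0
  at year 20).
* **Storm-effect window.** The storm-day multiplier applies while harvest
  flow alterations persist (post-harvest years 1–19). The storm mask is
  always computed on the *baseline* flow series (per analysis-year mean and
  sample SD), which keeps the combined scenario exactly decomposable:
  offsets add, multipliers multiply, turbidity passes through.

Climate offsets step annually (constant within an analysis year); flow
declines accumulate additively (0.25 × 63 = 15.75), not compounding.
Spin-up years are never transformed; scenario clocks start at analysis
year 1.

## The individual-based model

### Submodel forms

The daily schedule is: spawning, habitat selection, growth, survival, egg
development, then date advance (ages +1 on Jan 1). Submodel equations are
deliberately compact, with every coefficient in `IbmParams`:

* **Hydraulics**: power-law ratings per cell; depth < 1 cm ⇒ dry.
* **Drift intake**: encounter = drift concentration × velocity × capture
  area × daytime seconds, with capture area `20·(L/100)²` m² (a reaction
  field of roughly 0.5 m radius for a 25 cm fish, a few cm for fry) and a
  logistic capture success declining where velocity exceeds the sustainable
  swim speed (2 body lengths/s) and with turbidity (half-success at 30 NTU).
  Intake is capped by maximum consumption `0.10·W^0.8` g/d with a Gaussian
  thermal dome peaking at 14 °C, and by food remaining in the cell that day.
  A cell's daily drift food is the flux through its cross-section
  (concentration × v × d × w × daytime seconds), so drift supply scales with
  flow — one of the two channels behind the baseflow→adult-biomass
  sensitivity.
* **Search intake**: `0.06·W^0.8` g/d against an area-based benthic supply
  (0.15 g·m⁻²·d⁻¹). Search feeding is what fry rely on (their swim speed
  makes drift capture ineffective) and is a minor adult supplement, while
  drift feeding dominates for larger fish.
* **Metabolism**: `35·W^0.8·e^{0.07T}` J/d times an activity factor — for
  drift feeding `1 + v/v_max` with velocity shelter halving the activity
  surcharge; for search feeding a constant 1.3. Net energy converts to
  weight at 5900 J/g (food at 3500 J/g). Length increases only while
  condition `K = W/(0.01·L³)` is at 1 (surplus converts to length at K = 1);
  weight is floored at 10 % of reference weight.
* **Survival**: product of four logistic terms — terrestrial predation
  (risk up to 0.004/d; riskier when shallow relative to a 0.45 m midpoint,
  far from cover, and large), predation by larger trout (risk up to
  0.015/d for fish under ~5 cm when a fish ≥1.5× their length is present),
  starvation (half-survival at K = 0.6), and high temperature
  (half-survival at 25 °C, 1 °C width) — times a 0.2 stranding multiplier
  in dry cells. Expected fitness uses survival at the *projected* condition
  over a 90-day horizon; the realized daily draw uses post-growth state.
* **Spawning**: Apr 1–Jun 15, 5–17 °C, flow below 2× reference, females
  ≥ 12 cm, daily probability 0.1, once per calendar year (flags reset
  Jan 1). Spawners move to the reach's best gravel cell; fecundity
  `round(0.2·L^2.3)` (≈100 eggs at 15 cm); the female and the largest
  not-yet-spent male each lose 20 % of body weight. Restricting males to one
  spawning per season is a deliberate choice: an unrestricted "largest male
  every redd" rule compounds 20 % losses into systematic starvation of the
  largest males.
* **Eggs**: development accumulates `max(T,0)/450` degree-days; baseline
  egg mortality 0.05/d (≈10 % surviving a 45-day incubation), total loss on
  scour (flow > 10× reference) or desiccation (dry cell), extra mortality
  outside 2–16 °C. Completed redds release fry at `N(2.8, 0.2)` cm with
  weights at reference condition.

### Calibration of the defaults

The defaults were calibrated — in the same spirit in which the original
model family is calibrated to field sites — against the qualitative
behaviors this design requires of a small coastal stream, not against any
dataset: (i) a population persisting over 63+ simulated years at ~100–150
individuals with 13–30 age-3+ adults in a ~230 m reach (≈12 g/m² biomass,
high but plausible for productive coastal streams); (ii) recruitment
regulated by density dependence, i.e. large spring fry cohorts pruned by
food competition and size-dependent predation rather than by a cap; and
(iii) the documented sensitivity of adult biomass to baseflow, which in this
model flows through two channels — drift supply proportional to discharge
and terrestrial-predation risk declining with depth. The piscivory and
terrestrial-risk midpoints/widths are the main knobs controlling (i) and
(iii); the food concentrations control total carrying capacity.

### Determinism and the compiled kernel

One `numpy.random.Generator` per replicate drives all stochasticity in a
fixed daily order: spawning Bernoullis (ascending fish id), survival
uniforms, death-cause attribution, egg-mortality binomials (redd creation
order), fry lengths at emergence. Identical seed ⇒ bit-identical output.

The per-day hierarchy loop (habitat selection, growth, survival
probabilities) is JIT-compiled with numba. The scalar formulas
(`fitness_value`, `net_growth`, `survival_probability`) are shared between
the compiled loop and the pure-Python reference operations; the test suite
additionally asserts that the compiled loop's assignment equals a
brute-force argmax over the reference expected-fitness function, and that
its growth and survival outputs match the reference path to 1e-9. Ties in
habitat selection break to the lower cell id, fish-length ties to the lower
fish id. Dry-reach days send fish to the deepest cell at stranding risk.

## Response metrics

Seasons are summer (July–August) and winter (January–February); age classes
0, 1, 2, 3+ (3+ pools all older fish; winter has no age-0 class by the
Jan-1 ageing convention). From the 30-day-cadence snapshots: biomass is the
mean over in-season snapshots of summed weights; growth is the mean
fork-length change of individuals present at consecutive in-season
snapshots, scaled to cm per 30 days (survivors only, avoiding survivorship
composition artifacts); survival is the fraction of the class at the first
in-season snapshot alive at the last. Median emergence DOY is the smallest
day of year by which at least half the year's fry had emerged; years with
no emergence are missing values. Seasonal values are means over in-season
snapshots (the alternative — one snapshot per season — was rejected as
noisier at a 30-day cadence).

## Statistics

* **Mann-Kendall**: S with tie-corrected variance and the ±1 continuity
  correction. The serial-correlation correction is the effective-sample-size
  variance inflation computed from lag autocorrelations of the ranks of the
  Sen-detrended series, keeping only lags significant at two-sided α = 0.05
  (|ρ_k| > z₀.₉₇₅/√n). The factor is floored at 1 — it inflates variance
  under positive serial correlation but is never allowed to shrink it, since
  random negative sample autocorrelations on independent data would
  otherwise deflate the variance and push the type-I error above nominal.
  Sen slopes are medians of pairwise slopes, reported per decade. Users can
  disable the correction (`serial_correction=False`).
* **Kruskal-Wallis** goes through `scipy.stats.kruskal` (tie-corrected);
  all-identical pooled values return H = 0, p = 1.
* **Pairwise rank comparisons** are Nemenyi-type on joint mean ranks with a
  tie-corrected rank variance and a studentized-range reference
  (infinite df); the named procedure in this literature ("Tukey's test on
  ranks") has no single canonical form, and a type-I simulation in the test
  suite checks the realized level stays near nominal.
* **Wilcoxon signed-rank**: zero differences dropped (the classical and R
  convention), average ranks with tie-corrected variance, continuity-
  corrected normal p. The pseudomedian is the median of Walsh averages of
  the nonzero differences; the 95 % CI takes order statistics of the Walsh
  averages at exact signed-rank distribution quantiles (dynamic-program
  null CDF), so it is distribution-free.

## Pipeline

A `RunConfig` fixes streams, scenarios, horizon (67 years), spin-up discard
(4 years), replicates (5), snapshot cadence (30 days), harvest years (1, 41)
and the master seed. Per stream, the five observed water years and the reach
are generated from seeds derived from the master seed; the resampled year
ordering is drawn once per stream and shared by all scenarios, so scenarios
differ only by the regime transformation. Replicate seeds derive
deterministically (CRC-32 of the run key, < 2³¹) and are logged in the
provenance block; every output CSV embeds the config hash. The default
config is a single stream and the baseline scenario so that an end-to-end
run is desk-scale; the full four-stream, four-scenario design (optionally
expanded into temperature-only/flow-only variants) is expressed in the same
config. Trend windows are analysis years 1–20, 20–63 and 1–63; harvest
contrast periods are 1–40, 41–63 and 1–63.

## Problem sizes used in the checks

The emergent-behavior checks run the default synthetic stream for the full
67-year horizon (63 analysis years) with 5 replicates per arm — the same
replication the design prescribes — which keeps the whole suite within a
desktop-scale run. Under these conditions the climate scenario's emergence
trend is ≈ −2 days/decade; the direction (earlier emergence under warming)
is the tested property, while trend magnitudes depend on the synthetic
incubation regimes and are not comparable to field-calibrated values.

## Known limitations

* Single reach; no inter-stream movement (demographically negligible in the
  system this emulates), no other fish species, no food-supply response to
  temperature or harvest, no wood/shade geometry.
* One feeding mode per fish per day; daytime foraging only.
* Submodel coefficients are desk-scale calibrations, not field estimates;
  absolute biomass/growth/survival magnitudes should not be compared to
  field data.
* The regime generator produces stationary storm statistics within a water
  year and no multi-year hydrologic memory.
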