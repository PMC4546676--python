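# troutsim

An individual-based model (IBM) of stream-resident Coastal Cutthroat Trout
(*Oncorhynchus clarkii clarkii*) population dynamics in small coastal
headwater streams, together with the scenario machinery and nonparametric
statistics needed to ask: *how do trout populations respond to the changes in
stream temperature and flow expected from forest harvest and from climate
change — separately and combined — over six decades?*

The package is aimed at fish ecologists and quantitative stream ecologists
who want a self-contained, desk-scale version of this experimental design:
a daily-timestep IBM driven by temperature/flow/turbidity regimes, regime
transformations encoding harvest and warming scenarios, replicate
simulations, and trend/contrast statistics on the emergent responses.

## The model in brief

**Environment.** A stream reach is 210–250 m of channel split into 31–35
rectangular microhabitat cells, each with a power-law hydraulic rating
(depth `d = d_ref (Q/Q_ref)^β`, velocity likewise), velocity shelter,
spawning gravel, and distance to hiding cover. Daily inputs are flow *Q*
(m³/s), temperature *T* (°C), and turbidity (NTU). A synthetic-regime
generator emulates rain-dominated coastal hydrology — flashy Oct–Mar storm
flows, spring recession, extended summer low flow, temperatures ~6–12 °C —
and multi-decade inputs are built by resampling five observed water years
uniformly with replacement.

**Individuals.** Each trout carries length, weight, sex and age. Every day
the model executes, in order: **spawning → habitat selection → growth →
survival → egg development**. Fish select the cell and feeding mode (drift
or search) maximizing expected 90-day fitness,

&nbsp;&nbsp;&nbsp;&nbsp;`fitness = S_cell^90 × min(1, K_projected)`,

where `S_cell` is the combined daily survival the cell offers and
`K_projected` is the condition factor projected at the cell's net energy
intake. Selection runs in decreasing length order (a size hierarchy) and
consumed drift depletes what later fish can claim. Growth is a bioenergetics
budget (intake energy − metabolism, converted at tissue energy density);
survival multiplies four logistic risks (terrestrial predation, predation by
larger trout, starvation via condition, high temperature) plus stranding.
Redds accumulate degree-days and convert surviving eggs to age-0 fish at
completion; ages increment every January 1, so no age-0 fish exist in winter.

**Scenarios.** Transformations of the baseline regime series over a 67-year
horizon (first 4 years discarded as spin-up, leaving 63 analysis years):

* *Forest harvest* (cuts at analysis years 1 and 41): +0.37 °C for five
  post-harvest years, linear recovery of 0.037 °C/yr restoring baseline in
  year 16; summer (Jul–Sep) flows +45 % for five years with a linear ramp to
  baseline at year 20; +20 % water yield on storm days (baseline flow > 2 SD
  above the annual mean).
* *Climate change*: +0.06 °C per year (+3.78 °C at year 63); fall (Oct–Dec)
  flows −0.25 %-points/yr and winter (Jan–Mar) flows −0.49 %-points/yr
  (−15.75 % and −30.87 % at year 63).
* *Combined*: harvest first, then climate; offsets add, multipliers multiply.

**Statistics.** Kruskal-Wallis on ranks across scenarios with Nemenyi-type
pairwise comparisons; Mann-Kendall trend tests with tie-corrected variance,
continuity correction, serial-correlation variance inflation, and Sen slopes
per decade; Wilcoxon signed-rank (continuity-corrected) with the
Hodges–Lehmann pseudomedian and a distribution-based confidence interval.

## Worked example

Twelve simulated years on the "gus" preset (4 spin-up + 8 analysis years):

```python
from troutsim import environment as env, responses as resp
from troutsim.ibm import IbmParams, run_simulation
from troutsim.stats import mann_kendall

params = env.get_preset("gus")
reach = env.generate_reach(params, seed=42)
observed = env.split_years(env.generate_daily_regime(params, 5, seed=42))
sequence = env.resample_year_sequence(sorted(observed), 12, seed=42)
series = env.assemble_input_series(observed, sequence)

out = run_simulation(reach, series, IbmParams(), seed=0)
snaps = resp.annotate_years(out.snapshots, init_years=4)
print(resp.seasonal_summary(snaps, "summer", 3).head(4).to_string(index=False))
```

```
 year season  age_class   biomass_g  growth_cm_per_month  survival
    1 summer          3 1654.135778             0.058960  1.000000
    2 summer          3 1578.367297             0.073913  1.000000
    3 summer          3  803.785077             0.111064  1.000000
    4 summer          3 2264.422288             0.070694  0.909091
```

Each row is one analysis year: mean July–August biomass of age-3+ trout (g),
mean fork-length growth of surviving individuals (cm/month), and the fraction
of the age class present at the season's first snapshot still alive at its
last. The per-year median fry-emergence day of year and its trend:

```python
emerg = resp.yearly_emergence(out.emergence, init_years=4)
trend = mann_kendall(emerg["emergence_doy"].to_numpy())
print(f"Sen slope {trend.sen_slope:+.2f} days/decade, p = {trend.p:.2f}")
# Sen slope +3.33 days/decade, p = 0.62
```

Under the unmodified baseline the emergence trend is, as expected, not
distinguishable from zero over eight years; applying the climate scenario
(`troutsim.scenario.apply_scenario`) over the full 63-year horizon produces
consistently negative slopes (earlier emergence) of roughly −2 days/decade
under the default synthetic conditions.

The full stream × scenario × replicate design runs from one config:

```yaml
# experiment.yaml
streams: [gus, pothole, rock, um]       # presets, or directories with
scenarios: [baseline, harvest, climate, combined]   # regime.csv + reach.csv
separate_effects: true                  # adds temperature-/flow-only variants
replicates: 5
master_seed: 42
outdir: out
```

```bash
troutsim run --config experiment.yaml    # writes responses.csv, stats_*.csv ...
troutsim synthdata regime --preset gus --years 5 --seed 42 -o gus.csv
troutsim scenario apply --kind climate --in gus.csv --out gus_cc.csv
```

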