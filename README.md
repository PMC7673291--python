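# sporelife

Quantitative analysis of how dormant yeast spores age and die, at
single-spore-bag resolution.

Dormant *Saccharomyces cerevisiae* spores are not inert: they retain a slowly
fading ability to express genes, and that ability predicts whether a spore
bag (ascus) germinates when glucose appears. `sporelife` implements the full
analysis pipeline for this kind of data, from quantified per-spore-bag
fluorescence measurements to the kinetic model of dormancy-to-death:

* **Germination landscape** — the probability `P(germinate | glucose c,
  marker level x)` estimated as binned Bernoulli means over (glucose ×
  marker) pixels, with replicate averaging.
* **Dose-response** — a four-parameter logistic fitted on the log10-glucose
  axis, `f(c) = floor + (ceiling − floor) / (1 + (c50/c)^h)`, via weighted
  least squares (`DoseResponseModel.fit()` → `DoseResponseResults`).
* **Minimum glucose for germination** — binomial logistic regression of the
  per-bag outcome on log10 c within a marker bin, inverted at a target
  probability (default 0.99), with saturation / separation / extrapolation
  flags.
* **Trace kinetics** — per-spore fluorescence fold-change traces fitted with
  a flat-then-exponential model, `F(t) = exp(k (t − L))` for `t ≥ L`, the lag
  L profiled jointly with the rate k on the log scale; threshold-based lag
  detection; producing / non-producing classification.
* **Half-lives** — first 0.5-crossing of a relative decay or survival curve
  by linear interpolation (extrapolated, and flagged, when the curve never
  reaches one half).
* **Rate decomposition** — from a translation-inhibited half-life t_i and a
  drug-free half-life t_0: `k_deg = ln2/t_i`, `k_net = ln2/t_0`, relative
  production rate `p = k_deg − k_net`, characteristic production time `1/p`.
* **Threshold-death model** — per-spore pools with slow production and
  faster first-order degradation; a spore dies the first time any pool
  crosses its threshold. Closed-form death times, drug schedules, survival
  curves, and the implied ageing shift of the germination landscape
  (`ThresholdDeathModel.simulate()` → `DeathSimulationResults`).
* **Priming statistics** — Δτ (mean time to germinate after a glucose
  step-up), relative Δτ against a no-first-glucose control with a bootstrap
  CI, and per-module normalised-expression ratio tables.
* **Synthetic-data generator** — populations, traces, ageing series and
  priming datasets with the statistical structure the analysis assumes
  (lognormal capacity heterogeneity, capacity-coupled logistic germination,
  background fluorescence floor, additive noise), so the whole pipeline is
  testable without microscopy data.

## Worked example

```python
import numpy as np
import sporelife as sl
from sporelife import deathmodel as dm

# 1. dose-response on a synthetic population (3 replicates x 150 bags
#    at each of 8 glucose concentrations spanning 0.0002%..2%)
cfg = sl.GeneratorConfig(n_bags=150)
records = []
for rep in range(3):
    records += sl.generate_population(cfg, seed=1 + rep)
print(sl.DoseResponseModel.from_records(records).fit().summary())

# 2. production/degradation decomposition from a measured half-life pair
rates = sl.decompose_production(8.4, 14.0)
print(f"characteristic production time: "
      f"{rates.characteristic_production_time_days:.1f} days")

# 3. survival under translation inhibition in the threshold-death model
d = np.log(2) / 8.4
ratio = dm.median_ratio_for_dormancy_halflife(19.2, d)
species = dm.SpeciesParams("rnap2", 0.0, d, 1.0 / ratio, initial_cv=0.3)
sim = dm.ThresholdDeathModel(
    dm.DeathModelParams(species=(species,), n_spores=1000, seed=1)
).simulate(np.arange(0, 41, 4.0))
halflife, flag = sl.half_life_by_interpolation(
    sl.DecayCurve(sim.sample_days, sim.survival))
print(f"dormancy half-life: {halflife:.1f} days ({flag})")
```

prints

```
Dose-response fit (4-parameter logistic, log10 glucose axis)
  levels fitted     : 8
  c50 (% glucose)   : 0.0028848 (SE 6.7e-05)
  hill slope        : 2.44
  floor fraction    : 0.102
  ceiling fraction  : 0.998
  weighted RMS resid: 0.169
characteristic production time: 30.3 days
dormancy half-life: 18.9 days (interpolated)
```

The fitted c50 says half the spore bags germinate at ~0.003% glucose — the
sharp step of the population dose-response. The 30.3-day characteristic
production time is the reciprocal of the slow relative production rate of
RNA polymerase II during dormancy, obtained from how much a translation
inhibitor (8.4-day half-life) accelerates the drug-free net loss (14-day
half-life). The ~19-day dormancy half-life is the time for half the
simulated population to fall below its gene-expression threshold once
production is blocked.

A command-line interface mirrors the library:

```bash
sporelife generate --seed 1 --out records.csv
sporelife landscape --records records.csv --marker gfp_inducibility --bins 8 --out landscape.tsv
sporelife kinetics decompose --chx 8.4 --nodrug 14
sporelife simulate --days 0 --days 10 --days 20 --seed 7 --out survival.csv
sporelife run --out demo/ --seed 1
```

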