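# Methods

This note documents the models behind `sporelife`, the default parameters
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices that matter.

## The biological picture

The unit of observation is the spore bag (ascus): four genetically
identical haploid *S. cerevisiae* spores formed by one sporulating diploid.
A bag "germinates" when at least one spore buds a replicating cell after
glucose addition; operationally, a bag is *dormant* (alive) if it
germinates within 24 h of saturating (2% w/v) glucose and *dead* otherwise.
Three quantities are tied together:

1. a bag's latent **gene-expressing capacity**, proxied by GFP inducibility
   (the steady-state GFP a bag reaches under doxycycline induction without
   nutrients) and by RNA polymerase II level (an Rpb3–mCherry fusion);
2. its **germination ability**: the probability of germinating at each
   glucose concentration;
3. its **remaining lifespan** during nutrient-free ageing.

## Generative germination response

Per bag, germination is Bernoulli with

    p(c; x) = floor + (ceiling − floor) / (1 + (c50(x)/c)^h)
    c50(x)  = c50_ref · (x / x_ref)^(−γ)

logistic in log glucose c with a capacity-dependent midpoint; γ > 0 makes
the response monotone nondecreasing in both glucose and capacity, so the
landscape has the monotone "coastline" structure. Capacity x is lognormal
across bags (median 1,000 a.u., CV 0.4 — fluorescence histograms are broad
and right-skewed; no distribution family is dictated by the data, so
lognormal is a declared default, not an inference).

Defaults were calibrated once, numerically, against four population-level
anchors: the population dose-response midpoint at c50 ≈ 0.003% glucose; a
low-glucose plateau of ~10% germination; and, at 0.001% glucose,
near-certain germination in the top-inducibility bin but only ~10% in the
bin at half the maximal inducibility. This gives `c50_ref = 0.003`,
`hill_slope h = 14`, `capacity_coupling γ = 1.9`, `floor = 0.10`,
`ceiling = 1.0`. The steep per-bag hill matches the observation that, at
fixed inducibility, germination probability is a sharp step in glucose.
Note the floor bounds the half-maximal-inducibility pixel from below: with
a 10% per-bag floor, the expected measured value in that bin is ~10–11%
rather than exactly 10%.

Because log c50(x) is linear in log x and capacity is lognormal, the
population-average response is symmetric about log c50_ref, so the fitted
4PL midpoint is an unbiased estimate of `c50_ref` even though the mixture
is not itself a 4PL (it is shallower than the per-bag curve).

Marker levels (RNAP II, 18S rRNA, total new RNA) are lognormal with
level-scale Pearson correlations to capacity hit exactly by inverting the
lognormal correlation formula (defaults 0.64 / 0.5 / 0.24, the observed
marker–inducibility correlations). GFP inducibility is capacity times a 5%
multiplicative measurement noise.

## Traces

Post-glucose RNAP II traces are, for dormant bags, flat at baseline for a
lag L ~ Uniform(5, 10) h, then exponential growth at a per-bag rate
~ Normal(0.031, 0.010)/h, truncated at the germination time; dead bags
drift at −0.003/h. Raw fluorescence = background (2,500 a.u., the middle of
the observed 2,000–3,000 a.u. background range) + signal + Gaussian noise
(30 a.u.), floored at the background; frames every 10 min for 20 h. The
trace cohort emulates an aged population, whose surviving bags germinate
late in the movie: germination times Uniform(14, 20) h, chosen so every
dormant trace keeps a usable post-lag window (germination moments in such
movies are spread over the later part of the film).

**Fitting.** The exponential fit works on the log fold change with a
flat-then-linear model: y = 0 for t < L, y = k(t − L) for t ≥ L. The lag is
profiled over the frame grid (at least 5 post-lag points) and, per
candidate, the rate is the through-origin least-squares slope of the
shifted points; the (L, k) pair with minimal total SSE wins, ties toward
the earlier lag. Joint profiling rather than threshold-first fitting
matters for slow producers, whose growth may never clear a noise threshold
inside a truncated movie; the profiled fit stays unbiased there. Separate
threshold-based lag *detection* (first of k = 3 consecutive frames above
1 + 3σ/baseline, noise σ estimated from the first 6 frames) is kept as its
own operation for lag-time summaries. Frames at or below the background
floor are excluded; a trace entirely at the floor is flagged
`zero_information`. A trace is classified *producing* if k > 0.005/h with
R² > 0.3 — a cutoff placed an order of magnitude below the dormant group
mean (0.031/h) and well above the dead group mean (−0.003/h), since no
cutoff is dictated by the data.

## Half-lives and rate decomposition

Half-lives of population-mean decay curves (and of survival curves) are the
first 0.5-crossing located by linear interpolation between bracketing
samples; ties break toward the earlier time, and a curve that never reaches
0.5 is extrapolated linearly from its last two samples and flagged. On an
exponential sampled every Δ days the chord lies below the convex curve, so
the estimate is biased late by an amount that vanishes as Δ → 0 (about
+0.03 days at Δ = 2 for an 8.4-day half-life); this bias is
regression-tested.

The decomposition treats net loss as first-order: with translation blocked
the decay constant is the full degradation rate `k_deg = ln2/t_inhibited`;
drug-free, production offsets it to `k_net = ln2/t_nodrug`; the relative
production rate is `p = k_deg − k_net` and the characteristic production
time `1/p`. The ln2 (exponential-kinetics) conversion is the one under
which the measured 8.4-day / 14-day pair yields the 30.3-day characteristic
time; a plain reciprocal difference would give ~21 days instead.

## Threshold-death model

Each spore carries one or more molecular pools; death is the first time any
pool crosses its threshold (thresholds are per-species constants —
heterogeneity enters through lognormal initial levels; levels are in units
of the initial population median). Production is modelled per species as
either

* **zero-order** (default): constant production p against first-order
  degradation d, `M(t) = p/d + (M0 − p/d)e^{−dt}`, with the closed-form
  first crossing `t* = (1/d)·ln((M0 − p/d)/(T − p/d))` (infinite when the
  steady state p/d sits at or above T); or
* **first-order** (`production_order="first"`): production proportional to
  the current level, `M(t) = M0·e^{−(d−p)t}`.

The two regimes are not interchangeable: population means decay
exponentially — and the half-life-pair decomposition is exactly invertible —
only under first-order production (under zero-order, decomposing the two
cohort half-lives overestimates p by a factor approaching 1/ln2 even for
small p). The default two-species model therefore uses first-order
production for its pools, while the zero-order closed form is retained as
the canonical single-spore death-time primitive. Both are exposed and
tested.

Default two-species model: a slow **rnap2** pool (degradation half-life
8.4 d; production tuned so the drug-free net half-life is 14 d; threshold
1/6.6 of the initial median, which puts the drug-free dormancy half-life at
log2(6.6) × 14 ≈ 38 d) and a **fast transcript** pool (6-h molecular
half-life, production balancing degradation when unperturbed, threshold
0.25 — so zeroing its production kills half the population in ~12 h while
the rnap2 pool still holds >90% of its level). The fast pool is a model
hypothesis, not a measured species: it reproduces the observed dissociation
where transcription inhibition kills spores within hours even though their
RNAP II is still abundant. Drugs act multiplicatively on production within
scheduled windows (cycloheximide zeroes protein-pool production; thiolutin
zeroes all production).

Calibration helper: with production zeroed, a spore dies at `ln(M0/T)/d`,
so the median initial-to-threshold ratio that places the dormancy half-life
at H days is `exp(d·H)` (`median_ratio_for_dormancy_halflife`). For
d = ln2/8.4 and H = 19.2 d this gives ≈ 4.88.

The ageing pushforward (`predicted_landscape_shift`) identifies a species
level with capacity and maps the aged population through the generative
germination response, with dead spores at probability zero; at 2% glucose
the implied germinated fraction equals the survival fraction, which links
the survival assay to the landscape.

## Priming

Primed bags (exposed to a sub-germinating glucose pulse) germinate with
truncated-normal times of mean 120 min (vs 200 min unprimed, sd 30 min).
The priming effect is full for delays up to 48 h and decays linearly to
zero at 96 h, matching the observation that priming survives two days but
is gone by four. Δτ is the primed-cohort mean; relative Δτ divides by the
control mean, with a seeded percentile bootstrap CI (default 2,000
resamples). Module expression tables normalise each gene to its own 0-h
level (genes with nonpositive baselines are dropped, with the count
reported, rather than pseudocounted), average normalised levels per module
(arithmetic mean by default; geometric offered), and report the
primed/unprimed ratio — identically 1 at 0 h by construction. The shipped
module map is a placeholder; real analyses supply their own gene lists.

## Reproducibility and problem sizes

All generators are deterministic given (config, seed); sub-generators
derive their streams from the master seed by fixed offsets, so each dataset
is independently reproducible, and the pipeline manifest records the seed
and sha256 checksums of every artifact. The acceptance script uses 3 × 150
bags per concentration for the dose-response (10 seeds), 38 traces
(20 seeds), 1,000 spores (10 seeds) for the survival simulation, ~145 bags
(20 seeds) for the landscape pixel, and 100 bags per arm (20 seeds) for
priming — the study's own sample sizes, replicated over seeds to average
Monte Carlo noise.

## Limitations

* The generator emulates distributional structure, not microscopy: no
  segmentation artifacts, focal drift, photobleaching, spatial
  autocorrelation, or day effects. Passing tests validate the estimators on
  the assumed structure; they cannot certify behaviour under imaging
  systematics the generator does not contain.
* Germination-time distributions and the capacity distribution family are
  declared defaults (truncated normal / lognormal); the data constrain only
  means, spreads and qualitative shape.
* The fast-transcript species of the death model is hypothesised, not
  identified; its kinetics are set only by the ~12-h killing timescale.
* Germination times are generated independent of glucose concentration,
  although the real dependence is weak but nonzero (≤2-fold over a
  10,000-fold concentration range).
* The post-glucose production speed-up relative to dormancy is not modelled
  beyond what the trace and dormancy rates imply.
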