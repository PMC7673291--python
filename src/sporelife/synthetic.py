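"""Synthetic single-spore data generator.

Emulates the statistical structure of quantified spore-bag microscopy data:

* lognormal heterogeneity of gene-expressing capacity across spore bags,
* germination that is Bernoulli with a logistic-in-log-glucose probability
  whose midpoint shifts with capacity (:class:`~sporelife.germination.GerminationResponse`),
* fluorescent markers (GFP inducibility, RNAP II, rRNA, total new RNA)
  correlated with capacity at configurable Pearson targets,
* exponential ageing of capacity / RNAP II with condition-dependent rates
  (drug perturbations scale production),
* post-glucose fluorescence traces: a lag followed by exponential RNAP II
  production in dormant bags, flat or slowly decaying traces in dead bags,
  additive Gaussian noise on a background fluorescence floor,
* primed/unprimed germination-time cohorts and module-structured expression
  tables whose priming signature relaxes to parity within four days.

Everything is deterministic given (config, seed). Sub-generators derive
their streams from the master seed with fixed offsets so each dataset is
independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .germination import GerminationResponse
from .kinetics import TraceSeries
from .records import SporeBagRecord

__all__ = [
    "AgeingParams",
    "DrugEffect",
    "GeneratorConfig",
    "GerminationTimeParams",
    "PrimingDataset",
    "TraceParams",
    "generate_ageing_series",
    "generate_population",
    "generate_priming_dataset",
    "generate_trace_cohort",
    "generate_traces",
]

LN2 = math.log(2.0)

# fixed seed offsets so each sub-generator has an independent, reproducible
# stream derived from one master seed (all kept below 2**31)
_OFFSETS = {"population": 11, "traces": 23, "ageing": 37, "priming": 53}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng((int(seed) + _OFFSETS[stage]) % (2**31))


def _lognormal(rng, median: float, cv: float, size: int) -> np.ndarray:
    """Lognormal draws parameterised by median and coefficient of variation."""
    if cv == 0:
        return np.full(size, float(median))
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return median * np.exp(rng.normal(0.0, sigma, size))


def _log_sigma(cv: float) -> float:
    return math.sqrt(math.log(1.0 + cv * cv))


def _correlated_lognormal(
    rng, z_base: np.ndarray, median: float, cv: float, pearson_target: float
) -> np.ndarray:
    """Lognormal marker whose *level-scale* Pearson correlation with the
    (lognormal) base variable hits ``pearson_target``.

    Uses the exact relation between the normal-scale correlation rho and the
    lognormal-scale Pearson r:  r = (exp(rho*s1*s2) - 1) / sqrt((e^{s1^2}-1)(e^{s2^2}-1)).
    """
    s_base = np.std(z_base) if np.std(z_base) > 0 else 0.0
    s_m = _log_sigma(cv)
    if s_base == 0 or s_m == 0 or pearson_target == 0:
        rho = 0.0
    else:
        arg = 1.0 + pearson_target * math.sqrt(
            math.expm1(s_base**2) * math.expm1(s_m**2)
        )
        if arg <= 0:
            raise ValueError("pearson target unattainable for these CVs")
        rho = math.log(arg) / (s_base * s_m)
        rho = float(np.clip(rho, -1.0, 1.0))
    eps = rng.standard_normal(z_base.size)
    z_std = z_base / s_base if s_base > 0 else np.zeros_like(z_base)
    z_m = rho * z_std + math.sqrt(max(0.0, 1.0 - rho * rho)) * eps
    return median * np.exp(s_m * z_m)


# --------------------------------------------------------------------------
# configuration blocks


@dataclass(frozen=True)
class AgeingParams:
    """Exponential ageing of capacity / RNAP II.

    During drug-free dormancy the population-mean level halves every
    ``net_halflife_days`` (production partly offsets degradation); with
    translation fully inhibited it halves every ``degradation_halflife_days``.
    A bag is dead once its capacity falls below ``death_threshold_frac``
    times the initial median capacity.
    """

    net_halflife_days: float = 14.0
    degradation_halflife_days: float = 8.4
    death_threshold_frac: float = 1.0 / 6.6

    def __post_init__(self):
        if self.net_halflife_days <= 0 or self.degradation_halflife_days <= 0:
            raise ValueError("half-lives must be strictly positive")
        if not 0 < self.death_threshold_frac < 1:
            raise ValueError("death_threshold_frac must be in (0, 1)")

    @property
    def k_deg_per_day(self) -> float:
        return LN2 / self.degradation_halflife_days

    @property
    def k_net_per_day(self) -> float:
        return LN2 / self.net_halflife_days

    @property
    def production_per_day(self) -> float:
        return self.k_deg_per_day - self.k_net_per_day

    def decay_rate(self, production_scale: float) -> float:
        """Net first-order loss rate (1/day) when production is scaled."""
        return self.k_deg_per_day - production_scale * self.production_per_day


@dataclass(frozen=True)
class DrugEffect:
    production_scale: float = 1.0
    extra_death_rate_per_h: float = 0.0

    def __post_init__(self):
        if self.production_scale < 0:
            raise ValueError("production_scale must be >= 0")
        if self.extra_death_rate_per_h < 0:
            raise ValueError("extra_death_rate_per_h must be >= 0")


def _default_drug_effects() -> dict:
    return {
        "none": DrugEffect(1.0, 0.0),
        # cycloheximide blocks translation: no new RNAP II protein
        "cycloheximide": DrugEffect(0.0, 0.0),
        # thiolutin blocks transcription: no production, and fast-turnover
        # transcripts crash -> extra deaths with ~12 h half-life
        "thiolutin": DrugEffect(0.0, LN2 / 12.0),
    }


@dataclass(frozen=True)
class TraceParams:
    """Post-glucose RNAP II trace generation (Fig-5F-like movies).

    Dormant bags sit at baseline for a lag drawn uniformly from
    ``lag_h_range``, then grow exponentially at a per-bag rate drawn from
    Normal(production_rate_mean_per_h, production_rate_sd), truncated at
    germination. Dead bags drift exponentially at ``dead_drift_per_h``
    (<= 0). Raw fluorescence = background + signal + Gaussian noise, floored
    at the background.
    """

    lag_h_range: tuple = (5.0, 10.0)
    production_rate_mean_per_h: float = 0.031
    production_rate_sd: float = 0.010
    dead_drift_per_h: float = -0.003
    noise_sd_au: float = 30.0
    background_au: float = 2500.0
    frame_interval_min: float = 10.0
    duration_h: float = 20.0
    # aged dormant bags germinate late in the movie
    germination_window_h: tuple = (14.0, 20.0)

    def __post_init__(self):
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be strictly positive")
        if self.dead_drift_per_h > 0:
            raise ValueError("dead_drift_per_h must be <= 0")
        if self.noise_sd_au < 0 or self.background_au < 0:
            raise ValueError("noise_sd_au and background_au must be >= 0")
        if not self.lag_h_range[0] <= self.lag_h_range[1]:
            raise ValueError("lag_h_range must be (low, high) with low <= high")


@dataclass(frozen=True)
class GerminationTimeParams:
    """Truncated-normal germination times (minutes).

    Unprimed bags germinating in saturating glucose need ~200 min on
    average; bags primed by an earlier sub-germinating glucose pulse need
    ~120 min.
    """

    mean_unprimed_min: float = 200.0
    mean_primed_min: float = 120.0
    sd_min: float = 30.0

    def __post_init__(self):
        if self.mean_unprimed_min <= 0 or self.mean_primed_min <= 0:
            raise ValueError("mean germination times must be positive")
        if self.sd_min < 0:
            raise ValueError("sd_min must be >= 0")


def _default_glucose_levels() -> tuple:
    # eight log-spaced concentrations spanning the assayed 10,000-fold range
    return tuple(np.geomspace(2e-4, 2.0, 8))


def _default_marker_correlations() -> dict:
    # Pearson targets of marker level vs capacity on the level scale
    return {"rnap2_level": 0.64, "rrna_level": 0.5, "total_rna_rate": 0.24}


def _default_marker_cvs() -> dict:
    return {"rnap2_level": 0.4, "rrna_level": 0.4, "total_rna_rate": 0.4}


@dataclass(frozen=True)
class GeneratorConfig:
    """Full configuration of the synthetic-data generator."""

    n_bags: int = 150
    capacity_median: float = 1000.0
    capacity_cv: float = 0.4
    glucose_levels: tuple = field(default_factory=_default_glucose_levels)
    landscape: GerminationResponse = field(default_factory=GerminationResponse)
    ageing: AgeingParams = field(default_factory=AgeingParams)
    drug_effects: dict = field(default_factory=_default_drug_effects)
    traces: TraceParams = field(default_factory=TraceParams)
    germination_times: GerminationTimeParams = field(
        default_factory=GerminationTimeParams
    )
    marker_correlations: dict = field(default_factory=_default_marker_correlations)
    marker_cvs: dict = field(default_factory=_default_marker_cvs)
    gfp_noise_cv: float = 0.05
    censoring_horizon_min: float = 960.0
    priming_relaxation_start_h: float = 48.0
    priming_relaxation_end_h: float = 96.0
    seed: int = 0

    def __post_init__(self):
        if self.n_bags < 0:
            raise ValueError("n_bags must be >= 0")
        if self.capacity_cv < 0:
            raise ValueError("capacity_cv must be >= 0")
        if self.capacity_median <= 0:
            raise ValueError("capacity_median must be positive")
        if any(g <= 0 for g in self.glucose_levels):
            raise ValueError("glucose levels must be strictly positive")
        if self.gfp_noise_cv < 0:
            raise ValueError("gfp_noise_cv must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["glucose_levels"] = [float(g) for g in self.glucose_levels]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "landscape" in d and isinstance(d["landscape"], dict):
            d["landscape"] = GerminationResponse(**d["landscape"])
        if "ageing" in d and isinstance(d["ageing"], dict):
            d["ageing"] = AgeingParams(**d["ageing"])
        if "traces" in d and isinstance(d["traces"], dict):
            t = dict(d["traces"])
            for key in ("lag_h_range", "germination_window_h"):
                if key in t:
                    t[key] = tuple(t[key])
            d["traces"] = TraceParams(**t)
        if "germination_times" in d and isinstance(d["germination_times"], dict):
            d["germination_times"] = GerminationTimeParams(**d["germination_times"])
        if "drug_effects" in d:
            d["drug_effects"] = {
                k: DrugEffect(**v) if isinstance(v, dict) else v
                for k, v in d["drug_effects"].items()
            }
        if "glucose_levels" in d:
            d["glucose_levels"] = tuple(d["glucose_levels"])
        return cls(**d)


# --------------------------------------------------------------------------
# population


def _draw_capacities(rng, config: GeneratorConfig, n: int) -> np.ndarray:
    return _lognormal(rng, config.capacity_median, config.capacity_cv, n)


def _draw_markers(rng, config: GeneratorConfig, capacity: np.ndarray) -> dict:
    z = np.log(capacity / config.capacity_median)
    markers = {}
    for name, target in config.marker_correlations.items():
        cv = config.marker_cvs.get(name, 0.4)
        markers[name] = _correlated_lognormal(
            rng, z, config.capacity_median, cv, target
        )
    return markers


def _draw_germination_time(rng, mean_min: float, sd_min: float, size: int):
    """Normal germination times truncated at zero (resampled)."""
    t = rng.normal(mean_min, sd_min, size)
    while np.any(t <= 0):
        bad = t <= 0
        t[bad] = rng.normal(mean_min, sd_min, int(bad.sum()))
    return t


def generate_population(
    config: GeneratorConfig,
    seed: Optional[int] = None,
    glucose_levels=None,
) -> list[SporeBagRecord]:
    """Generate ``config.n_bags`` spore bags at each glucose level.

    Per bag: capacity ~ lognormal(median, cv); GFP inducibility =
    capacity x (1 + noise); marker levels correlated with capacity;
    germination drawn Bernoulli from the generative landscape. Germination
    times are truncated-normal and censored at the observation horizon.
    """
    if seed is None:
        seed = config.seed
    levels = config.glucose_levels if glucose_levels is None else tuple(glucose_levels)
    if any(g <= 0 for g in levels):
        raise ValueError("glucose levels must be strictly positive")
    rng = _rng(seed, "population")
    gt = config.germination_times
    records: list[SporeBagRecord] = []
    if config.n_bags == 0:
        return records
    for level_idx, glucose in enumerate(levels):
        n = config.n_bags
        capacity = _draw_capacities(rng, config, n)
        gfp = capacity * (1.0 + rng.normal(0.0, config.gfp_noise_cv, n))
        gfp = np.clip(gfp, 0.0, None)
        markers = _draw_markers(rng, config, capacity)
        p = config.landscape.prob(glucose, capacity)
        germinated = rng.random(n) < p
        times = _draw_germination_time(rng, gt.mean_unprimed_min, gt.sd_min, n)
        for i in range(n):
            germ = bool(germinated[i]) and times[i] <= config.censoring_horizon_min
            records.append(
                SporeBagRecord(
                    bag_id=f"g{level_idx}_b{i}",
                    glucose_pct=float(glucose),
                    germinated=germ,
                    germination_time_min=float(times[i]) if germ else None,
                    censoring_horizon_min=config.censoring_horizon_min,
                    capacity_true=float(capacity[i]),
                    gfp_inducibility=float(gfp[i]),
                    rnap2_level=float(markers["rnap2_level"][i]),
                    rrna_level=float(markers["rrna_level"][i]),
                    total_rna_rate=float(markers["total_rna_rate"][i]),
                )
            )
    return records


# --------------------------------------------------------------------------
# traces


def generate_traces(
    records: list[SporeBagRecord],
    config: GeneratorConfig,
    seed: Optional[int] = None,
) -> list[TraceSeries]:
    """Post-glucose RNAP II fold-change traces for the given records.

    A record is treated as dormant (alive) iff it germinated; dormant traces
    are truncated at the recorded germination time.
    """
    if seed is None:
        seed = config.seed
    tp = config.traces
    rng = _rng(seed, "traces")
    n_frames = int(round(tp.duration_h * 60.0 / tp.frame_interval_min)) + 1
    times_full = np.arange(n_frames) * tp.frame_interval_min / 60.0
    traces: list[TraceSeries] = []
    for rec in records:
        baseline_signal = rec.rnap2_level if rec.rnap2_level is not None else 1000.0
        if baseline_signal <= 0:
            baseline_signal = 1.0
        if rec.germinated and rec.germination_time_min is not None:
            t_end = rec.germination_time_min / 60.0
            times = times_full[times_full <= t_end]
        else:
            times = times_full
        if rec.germinated:
            lag = rng.uniform(*tp.lag_h_range)
            rate = rng.normal(tp.production_rate_mean_per_h, tp.production_rate_sd)
            growth = np.where(times < lag, 1.0, np.exp(rate * (times - lag)))
        else:
            growth = np.exp(tp.dead_drift_per_h * times)
        signal = baseline_signal * growth
        noise = rng.normal(0.0, tp.noise_sd_au, times.size) if tp.noise_sd_au else 0.0
        fluor = np.maximum(tp.background_au + signal + noise, tp.background_au)
        traces.append(
            TraceSeries(
                bag_id=rec.bag_id,
                times_h=times,
                fluor_au=fluor,
                baseline_au=tp.background_au + baseline_signal,
                background_au=tp.background_au,
                germination_time_h=(
                    rec.germination_time_min / 60.0
                    if rec.germination_time_min is not None
                    else None
                ),
            )
        )
    return traces


def generate_trace_cohort(
    config: GeneratorConfig,
    n_dormant: int,
    n_dead: int,
    seed: Optional[int] = None,
):
    """Aged-spore records plus their post-2%-glucose traces.

    Emulates the time-lapse experiment on an aged population: ``n_dormant``
    bags germinate late in the movie (uniform over
    ``traces.germination_window_h``) and rise exponentially after a lag,
    ``n_dead`` bags never germinate and drift at ``dead_drift_per_h``.

    Returns (records, traces).
    """
    if seed is None:
        seed = config.seed
    rng = _rng(seed, "traces")  # only used for record-level draws below
    tp = config.traces
    records: list[SporeBagRecord] = []
    horizon = tp.duration_h * 60.0
    lo, hi = tp.germination_window_h
    rnap2 = _lognormal(rng, config.capacity_median, config.capacity_cv, n_dormant + n_dead)
    for i in range(n_dormant):
        t_germ = rng.uniform(lo * 60.0, hi * 60.0)
        records.append(
            SporeBagRecord(
                bag_id=f"dormant_{i}",
                glucose_pct=2.0,
                germinated=True,
                germination_time_min=float(t_germ),
                censoring_horizon_min=horizon,
                rnap2_level=float(rnap2[i]),
                age_days=39.0,
            )
        )
    for i in range(n_dead):
        records.append(
            SporeBagRecord(
                bag_id=f"dead_{i}",
                glucose_pct=2.0,
                germinated=False,
                censoring_horizon_min=horizon,
                rnap2_level=float(rnap2[n_dormant + i]),
                age_days=39.0,
            )
        )
    traces = generate_traces(records, config, seed=seed + 1)
    return records, traces


# --------------------------------------------------------------------------
# ageing


def generate_ageing_series(
    config: GeneratorConfig,
    sample_days,
    condition: str = "none",
    seed: Optional[int] = None,
) -> dict[float, list[SporeBagRecord]]:
    """Age one population and sample it (with a 2%-glucose viability assay)
    on each of ``sample_days``.

    Capacity and RNAP II decay exponentially at the condition-dependent net
    rate; a bag is dead once its capacity falls below the death threshold or
    its drug-induced death time has passed. Germination outcome at 2% is
    alive x Bernoulli(landscape probability).
    """
    if seed is None:
        seed = config.seed
    sample_days = list(sample_days)
    if any(d < 0 for d in sample_days):
        raise ValueError("sample_days must be nonnegative")
    if sorted(sample_days) != sample_days:
        raise ValueError("sample_days must be sorted ascending")
    if condition not in config.drug_effects:
        raise ValueError(
            f"unknown condition {condition!r}; known: {sorted(config.drug_effects)}"
        )
    effect = config.drug_effects[condition]
    rate = config.ageing.decay_rate(effect.production_scale)
    rng = _rng(seed, "ageing")
    n = config.n_bags
    capacity0 = _draw_capacities(rng, config, n)
    rnap0 = _correlated_lognormal(
        rng,
        np.log(capacity0 / config.capacity_median),
        config.capacity_median,
        config.marker_cvs.get("rnap2_level", 0.4),
        config.marker_correlations.get("rnap2_level", 0.64),
    )
    threshold = config.ageing.death_threshold_frac * config.capacity_median
    if effect.extra_death_rate_per_h > 0:
        drug_death_days = rng.exponential(
            1.0 / (effect.extra_death_rate_per_h * 24.0), n
        )
    else:
        drug_death_days = np.full(n, np.inf)
    gt = config.germination_times
    out: dict[float, list[SporeBagRecord]] = {}
    for day in sample_days:
        decay = math.exp(-rate * day)
        capacity = capacity0 * decay
        rnap = rnap0 * decay
        alive = (capacity >= threshold) & (drug_death_days > day)
        p = config.landscape.prob(2.0, np.clip(capacity, 1e-300, None))
        germinated = alive & (rng.random(n) < p)
        times = _draw_germination_time(rng, gt.mean_unprimed_min, gt.sd_min, n)
        day_records = []
        for i in range(n):
            germ = bool(germinated[i]) and times[i] <= config.censoring_horizon_min
            day_records.append(
                SporeBagRecord(
                    bag_id=f"d{day}_b{i}",
                    glucose_pct=2.0,
                    germinated=germ,
                    germination_time_min=float(times[i]) if germ else None,
                    censoring_horizon_min=config.censoring_horizon_min,
                    capacity_true=float(capacity[i]),
                    gfp_inducibility=float(max(capacity[i], 0.0)),
                    rnap2_level=float(max(rnap[i], 0.0)),
                    age_days=float(day),
                    condition=condition,
                )
            )
        out[float(day)] = day_records
    return out


# --------------------------------------------------------------------------
# priming


@dataclass(frozen=True)
class PrimingDataset:
    primed_times_min: np.ndarray
    unprimed_times_min: np.ndarray
    expr_primed: pd.DataFrame
    expr_unprimed: pd.DataFrame
    module_map: pd.Series


#: Placeholder transcriptional modules used by the priming generator. Real
#: analyses supply their own gene -> module map.
_PRIMING_MODULES = {
    "glycolysis": 1.0,
    "ribosome_biogenesis": 0.6,
    "stress_response": -0.7,
    "spore_wall": -0.4,
    "translation": 0.3,
    "ncRNA_processing": -0.2,
}
_EXPR_TIMEPOINTS_H = (0.0, 16.0, 48.0, 96.0)


def _priming_weight(config: GeneratorConfig, delay_h: float) -> float:
    """Fraction of the full priming effect remaining after ``delay_h``.

    Full priming through ``priming_relaxation_start_h`` (primed up to two
    days), decaying linearly to zero at ``priming_relaxation_end_h`` (gone
    by four days).
    """
    start = config.priming_relaxation_start_h
    end = config.priming_relaxation_end_h
    if delay_h <= start:
        return 1.0
    if delay_h >= end:
        return 0.0
    return 1.0 - (delay_h - start) / (end - start)


def _module_shape(t_h: np.ndarray) -> np.ndarray:
    """Transient fold-change shape: 0 at 0 h, peak near 16 h, ~0 by 96 h."""
    t = np.asarray(t_h, dtype=float)
    return (t / 16.0) * np.exp(1.0 - t / 16.0)


def generate_priming_dataset(
    config: GeneratorConfig,
    delay_h: float,
    seed: Optional[int] = None,
    n_per_arm: int = 100,
    genes_per_module: int = 20,
    expr_noise_cv: float = 0.0,
) -> PrimingDataset:
    """Two-step-glucose synthetic experiment.

    Primed bags saw a sub-germinating glucose pulse, waited ``delay_h``
    hours, then received saturating glucose; unprimed controls waited in
    minimal medium without glucose. Germination times are truncated-normal;
    the priming acceleration decays with the delay and is gone by four days.
    Expression tables (genes x timepoints) carry module-structured fold
    changes, scaled by the same priming weight, that relax to parity by the
    longest timepoint.
    """
    if delay_h < 0:
        raise ValueError("delay_h must be >= 0")
    if seed is None:
        seed = config.seed
    rng = _rng(seed, "priming")
    gt = config.germination_times
    w = _priming_weight(config, delay_h)
    mean_primed = gt.mean_unprimed_min - w * (gt.mean_unprimed_min - gt.mean_primed_min)
    primed = _draw_germination_time(rng, mean_primed, gt.sd_min, n_per_arm)
    unprimed = _draw_germination_time(rng, gt.mean_unprimed_min, gt.sd_min, n_per_arm)

    t = np.asarray(_EXPR_TIMEPOINTS_H)
    shape = _module_shape(t)
    genes, modules, primed_rows, unprimed_rows = [], [], [], []
    for module, amplitude in _PRIMING_MODULES.items():
        base = _lognormal(rng, 100.0, 0.5, genes_per_module)
        for j in range(genes_per_module):
            gene = f"{module}_{j}"
            genes.append(gene)
            modules.append(module)
            fold = 1.0 + w * amplitude * shape
            noise_p = (
                1.0 + rng.normal(0.0, expr_noise_cv, t.size) if expr_noise_cv else 1.0
            )
            noise_u = (
                1.0 + rng.normal(0.0, expr_noise_cv, t.size) if expr_noise_cv else 1.0
            )
            primed_rows.append(base[j] * fold * noise_p)
            unprimed_rows.append(base[j] * np.ones_like(t) * noise_u)
    cols = [f"{int(tp)}h" for tp in t]
    expr_primed = pd.DataFrame(primed_rows, index=genes, columns=cols)
    expr_unprimed = pd.DataFrame(unprimed_rows, index=genes, columns=cols)
    module_map = pd.Series(modules, index=genes, name="module")
    return PrimingDataset(primed, unprimed, expr_primed, expr_unprimed, module_map)
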