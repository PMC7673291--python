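"""Forward threshold-death model of spore ageing.

Each spore carries pools of molecules required for gene expression (RNA
polymerase II, plus a hypothesised fast-turnover transcript pool). During
dormancy each pool is produced slowly and degrades faster, so levels fall;
a spore dies, permanently and irreversibly, the first time any pool drops
below its threshold. Drugs act by scaling production within scheduled
windows (cycloheximide removes protein production; thiolutin removes all
production).

Two production kinetics are supported per species:

* ``'zero'`` (default): constant production p (in units of the initial
  median level per day) against first-order degradation,
  ``M(t) = p/d + (M0 - p/d) * exp(-d t)``, with the closed-form first
  crossing of the threshold given by :func:`death_time_closed_form`.
* ``'first'``: production proportional to the current level,
  ``M(t) = M0 * exp(-(d - p) t)``, which reproduces the exponential decay
  of population means seen in chase experiments and is the regime in which
  the half-life pair decomposition (:func:`sporelife.kinetics.decompose_production`)
  is exact.

Levels are in units of the initial population median; thresholds are
fractions of that median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .germination import GerminationResponse

__all__ = [
    "DeathModelParams",
    "DeathSimulationResults",
    "DrugWindow",
    "SpeciesParams",
    "ThresholdDeathModel",
    "death_time_closed_form",
    "default_two_species",
    "level_closed_form",
    "median_ratio_for_dormancy_halflife",
    "predicted_landscape_shift",
]

LN2 = math.log(2.0)


def death_time_closed_form(M0: float, p: float, d: float, T: float) -> float:
    """First time ``M(t) = p/d + (M0 - p/d) exp(-d t)`` crosses ``T``.

    Returns 0 when the spore starts at or below threshold and ``inf`` when
    the steady state p/d sits at or above the threshold (the level
    approaches it asymptotically from above and never crosses).
    """
    if d <= 0:
        raise ValueError("degradation rate d must be strictly positive")
    if p < 0 or T <= 0:
        raise ValueError("p must be >= 0 and T > 0")
    if M0 <= T:
        return 0.0
    steady = p / d
    if T <= steady:
        return float("inf")
    return (1.0 / d) * math.log((M0 - steady) / (T - steady))


def _death_time_first_order(M0: float, p: float, d: float, T: float) -> float:
    """First threshold crossing under first-order production (net rate d-p)."""
    if M0 <= T:
        return 0.0
    net = d - p
    if net <= 0:
        return float("inf")
    return math.log(M0 / T) / net


def level_closed_form(M0, p: float, d: float, t, order: str = "zero"):
    """Level at time(s) ``t`` from initial level ``M0``."""
    t = np.asarray(t, dtype=float)
    M0 = np.asarray(M0, dtype=float)
    if order == "zero":
        if d == 0:
            return M0[..., None] + p * t
        steady = p / d
        return steady + (M0[..., None] - steady) * np.exp(-d * t)
    if order == "first":
        return M0[..., None] * np.exp(-(d - p) * t)
    raise ValueError("order must be 'zero' or 'first'")


def median_ratio_for_dormancy_halflife(
    dormancy_halflife_days: float, degradation_per_day: float
) -> float:
    """Median initial-level-to-threshold ratio that puts the dormancy
    half-life (time for half the population to die) at the given value,
    for a single species with production fully inhibited.

    With production zero every spore decays as ``M0 exp(-d t)`` and dies at
    ``ln(M0/T)/d``; the median death time is ``ln(median ratio)/d``, so the
    calibrated median ratio is ``exp(d * halflife)``.
    """
    if dormancy_halflife_days <= 0 or degradation_per_day <= 0:
        raise ValueError("half-life and degradation rate must be positive")
    return math.exp(degradation_per_day * dormancy_halflife_days)


@dataclass(frozen=True)
class SpeciesParams:
    """One molecular pool required for gene expression."""

    name: str
    production_per_day: float
    degradation_per_day: float
    threshold_frac: float
    initial_cv: float = 0.0
    production_order: str = "zero"  # 'zero' | 'first'

    def __post_init__(self):
        if self.degradation_per_day < 0:
            raise ValueError("degradation_per_day must be >= 0")
        if self.production_per_day < 0:
            raise ValueError("production_per_day must be >= 0")
        if not 0 < self.threshold_frac < 1:
            raise ValueError("threshold_frac must lie in (0, 1)")
        if self.initial_cv < 0:
            raise ValueError("initial_cv must be >= 0")
        if self.production_order not in ("zero", "first"):
            raise ValueError("production_order must be 'zero' or 'first'")


@dataclass(frozen=True)
class DrugWindow:
    """Production scaling applied between ``start_day`` and ``end_day``."""

    start_day: float
    end_day: float
    condition: str
    production_scale: dict  # species name -> scale factor

    def __post_init__(self):
        if self.end_day <= self.start_day:
            raise ValueError("end_day must exceed start_day")
        if any(s < 0 for s in self.production_scale.values()):
            raise ValueError("production scales must be >= 0")


@dataclass(frozen=True)
class DeathModelParams:
    species: tuple
    n_spores: int = 1000
    drug_schedule: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if len(self.species) == 0:
            raise ValueError("need at least one species")
        if self.n_spores < 1:
            raise ValueError("n_spores must be >= 1")
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        windows = sorted(self.drug_schedule, key=lambda w: w.start_day)
        for a, b in zip(windows, windows[1:]):
            if b.start_day < a.end_day:
                raise ValueError("drug-schedule windows must not overlap")


def default_two_species() -> tuple:
    """Default conceptual model: a slow RNA-polymerase pool plus a
    fast-turnover transcript pool.

    rnap2: degradation half-life 8.4 days; first-order production tuned so
    the drug-free net half-life is 14 days; threshold 1/6.6 of the initial
    median (putting the drug-free dormancy half-life near the observed
    ~38 days).

    fast_transcript: molecular half-life 6 h, production balancing
    degradation during unperturbed dormancy (steady), threshold 25% of the
    initial median -- so zeroing its production (transcription inhibition)
    kills half the population in ~12 h.
    """
    k_deg = LN2 / 8.4
    k_net = LN2 / 14.0
    rnap2 = SpeciesParams(
        name="rnap2",
        production_per_day=k_deg - k_net,
        degradation_per_day=k_deg,
        threshold_frac=1.0 / 6.6,
        initial_cv=0.4,
        production_order="first",
    )
    d_fast = LN2 / 0.25  # 6-hour molecular half-life
    fast = SpeciesParams(
        name="fast_transcript",
        production_per_day=d_fast,
        degradation_per_day=d_fast,
        threshold_frac=0.25,
        initial_cv=0.2,
        production_order="first",
    )
    return (rnap2, fast)


@dataclass(frozen=True)
class DeathSimulationResults:
    """Output of :meth:`ThresholdDeathModel.simulate`."""

    sample_days: np.ndarray
    death_days: np.ndarray  # per spore; inf if immortal
    survival: np.ndarray  # fraction alive at each sample day
    levels: dict  # species name -> (n_spores, n_days) array
    params: DeathModelParams

    @property
    def n_spores(self) -> int:
        return self.death_days.size

    def mean_levels(self, species: str, alive_only: bool = True) -> np.ndarray:
        """Population-mean level of one species at the sample days,
        restricted to spores still alive at each day by default (dead spores
        are not part of the dormant pool the chase experiments average)."""
        lv = self.levels[species]
        if not alive_only:
            return lv.mean(axis=0)
        alive = self.death_days[:, None] > self.sample_days[None, :]
        with np.errstate(invalid="ignore"):
            sums = np.where(alive, lv, 0.0).sum(axis=0)
            n = alive.sum(axis=0)
            return np.where(n > 0, sums / np.maximum(n, 1), np.nan)

    def summary(self) -> str:
        half = "n/a"
        below = np.nonzero(self.survival <= 0.5)[0]
        if below.size:
            half = f"~{self.sample_days[below[0]]:.3g} d (first sampled day at <= 50%)"
        lines = [
            "Threshold-death simulation",
            f"  spores            : {self.n_spores}",
            f"  species           : {', '.join(self.levels)}",
            f"  sample days       : {self.sample_days.min():.3g} .. {self.sample_days.max():.3g}",
            f"  final survival    : {self.survival[-1]:.3f}",
            f"  dormancy half-life: {half}",
        ]
        return "\n".join(lines)


class ThresholdDeathModel:
    """Forward simulator of the multi-species threshold-death model."""

    def __init__(self, params: DeathModelParams):
        self.params = params

    # -- schedule handling ------------------------------------------------
    def _segments(self, horizon: float):
        """Piecewise-constant production scaling up to ``horizon``.

        Yields (t_start, t_end, {species: scale}).
        """
        base = {s.name: 1.0 for s in self.params.species}
        edges = [0.0, horizon]
        for w in self.params.drug_schedule:
            edges += [w.start_day, w.end_day]
        edges = sorted({e for e in edges if 0.0 <= e <= horizon})
        for a, b in zip(edges, edges[1:]):
            scale = dict(base)
            for w in self.params.drug_schedule:
                if w.start_day <= a and b <= w.end_day:
                    scale.update(w.production_scale)
            yield a, b, scale

    # -- simulation --------------------------------------------------------
    def simulate(
        self, sample_days: Sequence[float], seed: Optional[int] = None
    ) -> DeathSimulationResults:
        """Simulate the population and sample levels / survival.

        Initial levels are lognormal with median 1 and the per-species CV;
        levels evolve by the closed form piecewise across drug-schedule
        segments; a spore dies at the first time any species crosses its
        threshold. Survival is the fraction with death time beyond each
        sample day.
        """
        sample_days = np.asarray(list(sample_days), dtype=float)
        if sample_days.size == 0 or np.any(sample_days < 0):
            raise ValueError("sample_days must be nonempty and nonnegative")
        if np.any(np.diff(sample_days) < 0):
            raise ValueError("sample_days must be sorted ascending")
        if seed is None:
            seed = self.params.seed
        rng = np.random.default_rng(int(seed) % (2**31))
        n = self.params.n_spores
        horizon = float(sample_days.max())

        levels0 = {}
        for sp in self.params.species:
            if sp.initial_cv == 0:
                levels0[sp.name] = np.ones(n)
            else:
                sigma = math.sqrt(math.log(1.0 + sp.initial_cv**2))
                levels0[sp.name] = np.exp(rng.normal(0.0, sigma, n))

        death = np.full(n, np.inf)
        level_samples = {sp.name: np.empty((n, sample_days.size)) for sp in self.params.species}
        current = {name: lv.copy() for name, lv in levels0.items()}

        segments = list(self._segments(horizon)) or [(0.0, horizon, {s.name: 1.0 for s in self.params.species})]
        for t0, t1, scales in segments:
            for sp in self.params.species:
                p_eff = sp.production_per_day * scales[sp.name]
                d = sp.degradation_per_day
                T = sp.threshold_frac
                M0 = current[sp.name]
                # sample levels at the sample days inside [t0, t1]
                inside = (sample_days >= t0) & (sample_days <= t1)
                if np.any(inside):
                    dt = sample_days[inside] - t0
                    level_samples[sp.name][:, inside] = level_closed_form(
                        M0, p_eff, d, dt, order=sp.production_order
                    )
                # threshold crossings within this segment
                if d == 0:
                    cross = np.where(M0 <= T, 0.0, np.inf)  # no degradation: immortal
                elif sp.production_order == "zero":
                    cross = np.array(
                        [death_time_closed_form(m, p_eff, d, T) for m in M0]
                    )
                else:
                    cross = np.array(
                        [_death_time_first_order(m, p_eff, d, T) for m in M0]
                    )
                in_seg = t0 + cross <= t1
                death = np.minimum(death, np.where(in_seg, t0 + cross, np.inf))
                # advance levels to the segment end
                current[sp.name] = level_closed_form(
                    M0, p_eff, d, np.array([t1 - t0]), order=sp.production_order
                )[:, 0]

        survival = (death[:, None] > sample_days[None, :]).mean(axis=0)
        # spores alive at t=0 by construction unless they start at/below threshold
        return DeathSimulationResults(
            sample_days=sample_days,
            death_days=death,
            survival=survival,
            levels=level_samples,
            params=self.params,
        )


def predicted_landscape_shift(
    results: DeathSimulationResults,
    response: GerminationResponse,
    glucose_grid,
    capacity_species: str = "rnap2",
    capacity_median: Optional[float] = None,
):
    """Implied population dose-response curves as the population ages.

    The designated species level (relative, median 1 at day 0) is identified
    with gene-expressing capacity and pushed through the generative
    germination response; dead spores germinate with probability zero.
    Returns an array of shape (n_days, n_glucose) of expected germinated
    fractions, one row per sample day of ``results``.
    """
    if capacity_species not in results.levels:
        raise ValueError(
            f"species {capacity_species!r} not simulated; have {sorted(results.levels)}"
        )
    if capacity_median is None:
        capacity_median = response.capacity_ref
    glucose = np.asarray(list(glucose_grid), dtype=float)
    levels = results.levels[capacity_species]
    alive = results.death_days[:, None] > results.sample_days[None, :]
    out = np.empty((results.sample_days.size, glucose.size))
    for j in range(results.sample_days.size):
        capacity = np.clip(levels[:, j], 1e-300, None) * capacity_median
        probs = response.prob(glucose[None, :], capacity[:, None])
        probs = np.where(alive[:, j][:, None], probs, 0.0)
        out[j] = probs.mean(axis=0)
    return out
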