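"""Single-trace and population kinetics.

Covers the kinetic measurements made on fluorescence data:

* per-trace exponential fits of post-glucose RNAP II fold change, with lag
  detection and a producing / non-producing classification,
* half-life estimation on population-mean decay curves (and survival
  curves) by first-crossing linear interpolation,
* decomposition of production vs degradation rates from a
  translation-inhibited / drug-free pair of half-lives,
* the operational dormant / dead call (germination within the horizon).

The rate decomposition assumes first-order loss: the level halves every
ln2/k days. With translation inhibited the decay rate is the full
degradation rate k_deg = ln2 / t_inhibited; without drugs production
partially offsets it, k_net = ln2 / t_nodrug, so the relative production
rate is k_deg - k_net and its reciprocal is the characteristic production
time. With the measured 8.4-day (cycloheximide) and 14-day (drug-free)
half-lives this gives ln2*(1/8.4 - 1/14) = 0.033/day, i.e. a characteristic
production time of ~30.3 days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "DecayCurve",
    "KineticRates",
    "TraceFit",
    "TraceSeries",
    "classify_dormant_dead",
    "decompose_production",
    "detect_lag",
    "fit_trace_cohort",
    "fit_trace_exponential",
    "half_life_by_interpolation",
]

LN2 = math.log(2.0)

#: classification cutoffs: a trace counts as "producing" only if its fitted
#: rate clears this positive rate with minimal fit support
PRODUCING_RATE_CUTOFF_PER_H = 0.005
PRODUCING_R2_CUTOFF = 0.3


@dataclass
class TraceSeries:
    """One spore bag's fluorescence time course.

    ``fold_change`` is the background-subtracted fluorescence relative to
    the (background-subtracted) pre-glucose baseline.
    """

    bag_id: str
    times_h: np.ndarray
    fluor_au: np.ndarray
    baseline_au: float
    background_au: float = 0.0
    germination_time_h: Optional[float] = None

    def __post_init__(self):
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.fluor_au = np.asarray(self.fluor_au, dtype=float)
        if self.times_h.ndim != 1 or self.times_h.shape != self.fluor_au.shape:
            raise ValueError("times_h and fluor_au must be 1-D and equal length")
        if self.times_h.size >= 2 and not np.all(np.diff(self.times_h) > 0):
            raise ValueError("times_h must be strictly increasing")
        if self.baseline_au <= self.background_au:
            raise ValueError("baseline must exceed the background floor")

    @property
    def net_baseline(self) -> float:
        return self.baseline_au - self.background_au

    @property
    def fold_change(self) -> np.ndarray:
        return (self.fluor_au - self.background_au) / self.net_baseline

    def __len__(self) -> int:
        return self.times_h.size


@dataclass(frozen=True)
class TraceFit:
    """Result of an exponential fit to one trace."""

    bag_id: str
    rate_per_h: float
    lag_h: Optional[float]
    r2: float
    classification: str  # 'producing' | 'non_producing'
    n_points: int
    flag: Optional[str] = None  # e.g. 'zero_information'


@dataclass(frozen=True)
class KineticRates:
    """Decay / production rates and derived characteristic times."""

    k_net_per_day: float
    k_deg_per_day: float
    production_per_day: float
    characteristic_production_time_days: float
    flag: Optional[str] = None  # 'no_production' | 'inconsistent' | None


@dataclass(frozen=True)
class DecayCurve:
    """Relative-level (or survival-fraction) samples over time in days."""

    sample_days: np.ndarray
    level_rel: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "sample_days", np.asarray(self.sample_days, float))
        object.__setattr__(self, "level_rel", np.asarray(self.level_rel, float))
        if self.sample_days.shape != self.level_rel.shape or self.sample_days.ndim != 1:
            raise ValueError("sample_days and level_rel must be 1-D and equal length")
        if not np.all(np.isfinite(self.level_rel)):
            raise ValueError("decay curve contains non-finite values")
        if np.any(self.level_rel < 0):
            raise ValueError("levels must be nonnegative")


def detect_lag(
    trace: TraceSeries,
    noise_sd_au: Optional[float] = None,
    k_frames: int = 3,
    baseline_frames: int = 6,
) -> Optional[float]:
    """Time at which production becomes detectable.

    The lag is the first time the fold change exceeds
    ``1 + 3 * noise_sd / net_baseline`` for ``k_frames`` consecutive frames.
    The noise level is estimated from the first ``baseline_frames`` frames
    unless given. Returns ``None`` if the threshold is never held.
    """
    if len(trace) < baseline_frames + k_frames:
        raise ValueError(
            f"trace {trace.bag_id!r}: need >= {baseline_frames + k_frames} frames"
        )
    fold = trace.fold_change
    if noise_sd_au is None:
        net = trace.fluor_au[:baseline_frames] - trace.background_au
        noise_sd_au = float(np.std(net, ddof=1))
    threshold = 1.0 + 3.0 * noise_sd_au / trace.net_baseline
    above = fold > threshold
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= k_frames:
            return float(trace.times_h[i - k_frames + 1])
    return None


def _profile_lag_fit(t: np.ndarray, y: np.ndarray, min_tail: int = 5):
    """Least-squares fit of the lag-then-exponential model on the log scale.

    Model: y = 0 for t < lag, y = rate * (t - lag) for t >= lag (the fold
    change is anchored at 1 during the lag). The lag is profiled over the
    observed frame times, keeping at least ``min_tail`` post-lag points;
    for each candidate the rate is the through-origin regression slope of
    the shifted post-lag points. Returns (rate, lag, sse); ties break
    toward the earliest lag.
    """
    n = t.size
    last = n - min_tail if n > min_tail else 0
    best = None
    for i in range(0, max(last, 0) + 1):
        lag = t[i]
        x = t[i:] - lag
        yy = y[i:]
        sxx = float(np.dot(x, x))
        rate = float(np.dot(x, yy) / sxx) if sxx > 0 else 0.0
        sse = float(np.sum(y[:i] ** 2)) + float(np.sum((yy - rate * x) ** 2))
        if best is None or sse < best[2] - 1e-12:
            best = (rate, float(lag), sse)
    return best


def fit_trace_exponential(
    trace: TraceSeries,
    fit_window_h: Optional[tuple] = None,
    rate_cutoff_per_h: float = PRODUCING_RATE_CUTOFF_PER_H,
    r2_cutoff: float = PRODUCING_R2_CUTOFF,
) -> TraceFit:
    """Exponential fit of a trace's fold change, jointly with the lag.

    The log fold change is fitted with a flat-then-linear model (flat at 1
    during the lag, exponential growth or decay afterwards); the lag is
    profiled over the frame grid and the rate is least-squares within each
    profile. Frames at or below the background floor are excluded and the
    fit is truncated at the germination time when present. A trace whose
    best lag is the first frame is reported with ``lag_h = None`` (no
    detectable lag; flat or monotone traces fit this way).
    """
    times = trace.times_h
    fold = trace.fold_change
    if trace.germination_time_h is not None:
        keep = times <= trace.germination_time_h
        times, fold = times[keep], fold[keep]
    if fit_window_h is not None:
        keep = (times >= fit_window_h[0]) & (times <= fit_window_h[1])
        times, fold = times[keep], fold[keep]
    positive = fold > 0
    t, y = times[positive], np.log(fold[positive])
    if t.size < 2 or np.ptp(t) == 0:
        return TraceFit(
            trace.bag_id,
            float("nan"),
            None,
            float("nan"),
            "non_producing",
            int(t.size),
            flag="zero_information",
        )
    rate, lag, sse = _profile_lag_fit(t, y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else 1.0
    producing = rate > rate_cutoff_per_h and r2 > r2_cutoff
    lag_out = lag if lag > t[0] else None
    return TraceFit(
        trace.bag_id,
        float(rate),
        lag_out,
        float(r2),
        "producing" if producing else "non_producing",
        int(t.size),
    )


def fit_trace_cohort(traces, **kwargs):
    """Fit every trace; returns a pandas DataFrame, one row per bag."""
    import pandas as pd

    fits = [fit_trace_exponential(tr, **kwargs) for tr in traces]
    return pd.DataFrame(
        {
            "bag_id": [f.bag_id for f in fits],
            "rate_per_h": [f.rate_per_h for f in fits],
            "lag_h": [f.lag_h for f in fits],
            "r2": [f.r2 for f in fits],
            "classification": [f.classification for f in fits],
            "n_points": [f.n_points for f in fits],
            "flag": [f.flag for f in fits],
        }
    )


def half_life_by_interpolation(curve: DecayCurve) -> tuple[float, str]:
    """Time of the first 0.5-crossing of a relative-level or survival curve.

    The crossing is located by linear interpolation between the bracketing
    samples (ties broken toward the earlier time). If no sample is below
    0.5, the crossing is extrapolated linearly from the last two samples and
    flagged. Raises if the curve never heads downward through 0.5.
    """
    t, y = curve.sample_days, curve.level_rel
    if t.size < 2:
        raise ValueError("need at least two samples")
    if not math.isclose(y[0], 1.0, rel_tol=1e-6):
        raise ValueError("curve must be normalized to 1 at its first sample")
    # first sample at or below one half (first crossing; ties -> earlier)
    below = np.nonzero(y <= 0.5)[0]
    if below.size:
        j = int(below[0])
        if y[j] == 0.5:
            return float(t[j]), "interpolated"
        i = j - 1
        frac = (y[i] - 0.5) / (y[i] - y[j])
        return float(t[i] + frac * (t[j] - t[i])), "interpolated"
    slope = (y[-1] - y[-2]) / (t[-1] - t[-2])
    if slope >= 0:
        raise ValueError("curve does not cross 0.5 and is not decreasing at its end")
    return float(t[-1] + (0.5 - y[-1]) / slope), "extrapolated"


def decompose_production(
    halflife_inhibited_days: float, halflife_no_drug_days: float
) -> KineticRates:
    """Production / degradation decomposition from a half-life pair.

    ``halflife_inhibited_days`` is measured with translation blocked (pure
    degradation), ``halflife_no_drug_days`` without drugs (net loss =
    degradation - production).
    """
    if halflife_inhibited_days <= 0 or halflife_no_drug_days <= 0:
        raise ValueError("half-lives must be strictly positive")
    k_deg = LN2 / halflife_inhibited_days
    k_net = LN2 / halflife_no_drug_days
    production = k_deg - k_net
    if production > 0:
        tau = 1.0 / production
        flag = None
    elif production == 0:
        tau = float("inf")
        flag = "no_production"
    else:
        tau = float("inf")
        flag = "inconsistent"  # inhibited half-life exceeded the drug-free one
    return KineticRates(k_net, k_deg, production, tau, flag)


@dataclass(frozen=True)
class DormancyCall:
    label: str  # 'dormant' | 'dead' | 'unlabeled'
    trace_classification: Optional[str]
    concordant: Optional[bool]
    flag: Optional[str] = None


def classify_dormant_dead(
    fit: Optional[TraceFit],
    germinated_within_horizon: Optional[bool],
    horizon_h: float = 24.0,
) -> DormancyCall:
    """Operational dormant/dead call.

    A spore bag that germinates within the observation horizon (>= 24 h at
    saturating glucose) is dormant (alive); one that does not is dead. The
    trace classification is reported alongside for concordance statistics
    (dormant <-> producing); a producing trace on a dead bag is flagged.
    """
    if horizon_h < 24.0:
        raise ValueError("observation horizon must be >= 24 h")
    if germinated_within_horizon is None:
        return DormancyCall("unlabeled", fit.classification if fit else None, None)
    label = "dormant" if germinated_within_horizon else "dead"
    trace_class = fit.classification if fit is not None else None
    concordant = None
    flag = None
    if trace_class is not None:
        expected = "producing" if label == "dormant" else "non_producing"
        concordant = trace_class == expected
        if not concordant:
            flag = "discordant"
    return DormancyCall(label, trace_class, concordant, flag)
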