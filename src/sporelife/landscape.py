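"""Germination-landscape estimation and dose-response statistics.

The germination landscape is the matrix of germination probabilities over
(glucose concentration x marker bin): each pixel is the fraction of spore
bags, within one marker bin at one glucose concentration, that germinated.
Population-level germinated fractions vs glucose are summarised by a
four-parameter logistic (4PL) on the log10-glucose axis, and the minimum
glucose concentration guaranteeing germination for one marker bin is read
off a binomial logistic regression ("log-regression") of the per-bag
outcome on log10 glucose.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .records import SporeBagRecord, records_to_frame

__all__ = [
    "AssociationResult",
    "BinnedProbability",
    "DoseResponseModel",
    "DoseResponseResults",
    "LandscapeGrid",
    "MinGlucoseResult",
    "average_landscapes",
    "bin_probability",
    "default_bin_edges",
    "estimate_landscape",
    "fit_dose_response",
    "min_glucose_for_germination",
    "pearson_association",
]

#: bins with fewer records than this are reported but flagged unreliable
DEFAULT_MIN_COUNT = 5


def _marker_values(records, marker: str) -> tuple[np.ndarray, np.ndarray]:
    values = np.array([getattr(r, marker) for r in records], dtype=float)
    germ = np.array([r.germinated for r in records], dtype=bool)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"marker {marker!r} contains non-finite values")
    return values, germ


def default_bin_edges(values, n_bins: int = 8, span_pct=(1.0, 99.0)) -> np.ndarray:
    """Equal-width bin edges spanning the 1st-99th percentile of the marker."""
    lo, hi = np.percentile(np.asarray(values, float), span_pct)
    if hi <= lo:
        raise ValueError("degenerate marker range")
    return np.linspace(lo, hi, n_bins + 1)


@dataclass(frozen=True)
class BinnedProbability:
    marker_name: str
    bin_edges: np.ndarray
    prob: np.ndarray  # nan where count == 0
    counts: np.ndarray
    reliable: np.ndarray  # count >= min_count

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def bin_probability(
    records: Sequence[SporeBagRecord],
    marker: str = "gfp_inducibility",
    bin_edges=None,
    n_bins: int = 8,
    min_count: int = DEFAULT_MIN_COUNT,
) -> BinnedProbability:
    """Germinated fraction per marker bin.

    Records outside the outermost edges are clipped into the end bins (the
    default edges span the 1st-99th percentile, so tail bags land in the
    extreme bins). Bins with fewer than ``min_count`` records are flagged
    unreliable but still reported; empty bins get ``nan``.
    """
    values, germ = _marker_values(records, marker)
    if bin_edges is None:
        bin_edges = default_bin_edges(values, n_bins=n_bins)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if bin_edges.ndim != 1 or bin_edges.size < 2 or np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 entries")
    nb = bin_edges.size - 1
    idx = np.clip(np.digitize(values, bin_edges) - 1, 0, nb - 1)
    counts = np.bincount(idx, minlength=nb)
    hits = np.bincount(idx, weights=germ.astype(float), minlength=nb)
    with np.errstate(invalid="ignore"):
        prob = np.where(counts > 0, hits / np.maximum(counts, 1), np.nan)
    return BinnedProbability(
        marker_name=marker,
        bin_edges=bin_edges,
        prob=prob,
        counts=counts.astype(int),
        reliable=counts >= min_count,
    )


@dataclass(frozen=True)
class LandscapeGrid:
    """Germination probability over glucose (rows) x marker bins (columns)."""

    marker_name: str
    glucose_levels: np.ndarray
    bin_edges: np.ndarray
    prob: np.ndarray  # shape (n_levels, n_bins); nan where empty
    counts: np.ndarray
    reliable: np.ndarray
    n_replicates: np.ndarray = None  # per-pixel replicate count when averaged

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def estimate_landscape(
    records: Sequence[SporeBagRecord],
    marker: str = "gfp_inducibility",
    bin_edges=None,
    glucose_levels=None,
    n_bins: int = 8,
    min_count: int = DEFAULT_MIN_COUNT,
) -> LandscapeGrid:
    """Estimate the germination landscape from per-bag records.

    One row of :func:`bin_probability` per glucose level, on shared marker
    bin edges (derived from the pooled marker distribution by default).
    """
    values, _ = _marker_values(records, marker)
    if bin_edges is None:
        bin_edges = default_bin_edges(values, n_bins=n_bins)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if glucose_levels is None:
        glucose_levels = sorted({r.glucose_pct for r in records})
    glucose_levels = np.asarray(list(glucose_levels), dtype=float)
    nb = bin_edges.size - 1
    prob = np.full((glucose_levels.size, nb), np.nan)
    counts = np.zeros((glucose_levels.size, nb), dtype=int)
    reliable = np.zeros((glucose_levels.size, nb), dtype=bool)
    for i, level in enumerate(glucose_levels):
        subset = [r for r in records if r.glucose_pct == level]
        if not subset:
            continue
        row = bin_probability(
            subset, marker=marker, bin_edges=bin_edges, min_count=min_count
        )
        prob[i], counts[i], reliable[i] = row.prob, row.counts, row.reliable
    return LandscapeGrid(marker, glucose_levels, bin_edges, prob, counts, reliable)


def average_landscapes(grids: Sequence[LandscapeGrid]) -> LandscapeGrid:
    """Replicate-averaged landscape: each pixel is the mean of the replicate
    pixel probabilities (empty replicate pixels are skipped); the per-pixel
    replicate count is retained. All grids must share axes.
    """
    if not grids:
        raise ValueError("need at least one landscape")
    first = grids[0]
    for g in grids[1:]:
        if not (
            np.array_equal(g.glucose_levels, first.glucose_levels)
            and np.array_equal(g.bin_edges, first.bin_edges)
        ):
            raise ValueError("landscapes must share glucose levels and bin edges")
    stack = np.stack([g.prob for g in grids])
    counts = np.stack([g.counts for g in grids]).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        prob = np.nanmean(stack, axis=0)
    n_rep = np.sum(~np.isnan(stack), axis=0)
    reliable = counts >= DEFAULT_MIN_COUNT * len(grids)
    return LandscapeGrid(
        first.marker_name,
        first.glucose_levels,
        first.bin_edges,
        prob,
        counts,
        reliable,
        n_replicates=n_rep,
    )


# --------------------------------------------------------------------------
# population dose-response (4PL on log10 glucose)


def _four_pl(log10_c, floor, ceiling, log10_c50, hill):
    return floor + (ceiling - floor) / (1.0 + 10.0 ** (hill * (log10_c50 - log10_c)))


@dataclass(frozen=True)
class DoseResponseResults:
    """Fitted four-parameter logistic dose-response."""

    c50: float
    hill_slope: float
    floor_frac: float
    ceiling_frac: float
    fit_residual: float  # weighted RMS residual
    covariance: np.ndarray  # order: floor, ceiling, log10_c50, hill
    n_levels: int

    @property
    def c50_se(self) -> float:
        """Approximate standard error of c50 (delta method from log10 c50)."""
        var_log = self.covariance[2, 2]
        return float(self.c50 * math.log(10.0) * math.sqrt(max(var_log, 0.0)))

    def summary(self) -> str:
        lines = [
            "Dose-response fit (4-parameter logistic, log10 glucose axis)",
            f"  levels fitted     : {self.n_levels}",
            f"  c50 (% glucose)   : {self.c50:.5g} (SE {self.c50_se:.2g})",
            f"  hill slope        : {self.hill_slope:.3g}",
            f"  floor fraction    : {self.floor_frac:.3g}",
            f"  ceiling fraction  : {self.ceiling_frac:.3g}",
            f"  weighted RMS resid: {self.fit_residual:.3g}",
        ]
        return "\n".join(lines)

    def predict(self, glucose_pct) -> np.ndarray:
        return _four_pl(
            np.log10(np.asarray(glucose_pct, float)),
            self.floor_frac,
            self.ceiling_frac,
            math.log10(self.c50),
            self.hill_slope,
        )


class DoseResponseModel:
    """Population germinated fraction vs glucose concentration.

    Weighted least-squares fit of
    ``f(c) = floor + (ceiling - floor) / (1 + (c50/c)**h)`` on the log10
    glucose axis. The fit is initialised from the concentration bracketing
    the midpoint of the observed fractions.
    """

    def __init__(self, glucose_pct, fraction, weights=None):
        self.glucose = np.asarray(glucose_pct, dtype=float)
        self.fraction = np.asarray(fraction, dtype=float)
        if self.glucose.shape != self.fraction.shape:
            raise ValueError("glucose and fraction must have equal length")
        if np.any(self.glucose <= 0):
            raise ValueError("glucose concentrations must be positive")
        if np.any((self.fraction < 0) | (self.fraction > 1)):
            raise ValueError("fractions must lie in [0, 1]")
        if np.unique(self.glucose).size < 4:
            raise ValueError("need >= 4 distinct glucose levels spanning the step")
        self.weights = (
            np.ones_like(self.fraction) if weights is None else np.asarray(weights, float)
        )

    @classmethod
    def from_records(cls, records: Sequence[SporeBagRecord]) -> "DoseResponseModel":
        """Aggregate per-bag records to per-level germinated fractions,
        weighted by the number of bags at each level."""
        frame = records_to_frame(records)
        grouped = frame.groupby("glucose_pct")["germinated"].agg(["mean", "size"])
        return cls(grouped.index.values, grouped["mean"].values, grouped["size"].values)

    def _initial_params(self):
        order = np.argsort(self.glucose)
        c, f = self.glucose[order], self.fraction[order]
        floor0, ceiling0 = float(f.min()), float(f.max())
        mid = 0.5 * (floor0 + ceiling0)
        above = np.nonzero(f >= mid)[0]
        below = np.nonzero(f < mid)[0]
        if above.size and below.size:
            # bracket the midpoint: geometric mean of the flanking levels
            i_hi = int(above[0]) if above[0] > 0 else int(above[-1])
            i_lo = max(i_hi - 1, 0)
            x50 = 0.5 * (math.log10(c[i_lo]) + math.log10(c[i_hi]))
        else:
            x50 = float(np.mean(np.log10(c)))
        return [floor0, ceiling0, x50, 2.0]

    def fit(self) -> DoseResponseResults:
        if np.allclose(self.fraction, self.fraction[0]):
            raise ValueError("all fractions equal: no dose-response transition to fit")
        x = np.log10(self.glucose)
        sigma = 1.0 / np.sqrt(self.weights)
        p0 = self._initial_params()
        bounds = (
            [0.0, 0.0, x.min() - 2.0, 0.05],
            [1.0, 1.0, x.max() + 2.0, 200.0],
        )
        try:
            popt, pcov = optimize.curve_fit(
                _four_pl,
                x,
                self.fraction,
                p0=p0,
                sigma=sigma,
                absolute_sigma=False,
                bounds=bounds,
                maxfev=20000,
            )
        except RuntimeError as err:
            resid = self.fraction - _four_pl(x, *p0)
            raise RuntimeError(
                f"dose-response fit did not converge: {err}; "
                f"residuals at start {np.round(resid, 4).tolist()}"
            ) from err
        floor, ceiling, x50, hill = popt
        resid = (self.fraction - _four_pl(x, *popt)) * np.sqrt(self.weights)
        rms = float(np.sqrt(np.mean(resid**2)))
        if ceiling < floor:  # canonicalise
            floor, ceiling = ceiling, floor
        return DoseResponseResults(
            c50=float(10.0**x50),
            hill_slope=float(hill),
            floor_frac=float(floor),
            ceiling_frac=float(ceiling),
            fit_residual=rms,
            covariance=pcov,
            n_levels=int(np.unique(self.glucose).size),
        )


def fit_dose_response(fractions) -> DoseResponseResults:
    """Functional wrapper: ``fractions`` is an iterable of
    (glucose_pct, germinated_fraction[, weight]) tuples."""
    rows = [tuple(row) for row in fractions]
    glucose = [r[0] for r in rows]
    frac = [r[1] for r in rows]
    weights = [r[2] if len(r) > 2 else 1.0 for r in rows]
    return DoseResponseModel(glucose, frac, weights).fit()


# --------------------------------------------------------------------------
# minimum glucose for (near-)guaranteed germination


@dataclass(frozen=True)
class MinGlucoseResult:
    concentration_pct: float
    target_p: float
    flag: str  # 'fitted' | 'extrapolated' | 'lower_bound' | 'separation'
    slope: Optional[float] = None
    intercept: Optional[float] = None


def min_glucose_for_germination(
    glucose_pct,
    germinated,
    target_p: float = 0.99,
) -> MinGlucoseResult:
    """Minimum glucose concentration at which the fitted germination
    probability reaches ``target_p`` for one marker bin.

    Per-bag outcomes within the bin are regressed on log10(glucose) with a
    binomial logistic model; the returned concentration is the fitted
    inverse at ``target_p``. Saturated bins (every bag germinated) yield a
    lower bound at the smallest tested concentration; perfectly separated
    outcomes yield the separation boundary, flagged, rather than a fitted
    value.
    """
    import statsmodels.api as sm

    glucose = np.asarray(glucose_pct, dtype=float)
    outcome = np.asarray(germinated).astype(float)
    if glucose.shape != outcome.shape:
        raise ValueError("glucose and outcomes must have equal length")
    if np.any(glucose <= 0):
        raise ValueError("glucose concentrations must be positive")
    if not 0 < target_p < 1:
        raise ValueError("target_p must be in (0, 1)")
    levels = np.unique(glucose)
    if levels.size < 3:
        raise ValueError("need >= 3 glucose levels with defined outcomes")
    if outcome.max() == 0:
        raise ValueError("no germinations in this bin: target unreachable")
    if outcome.min() == 1:
        return MinGlucoseResult(float(levels.min()), target_p, "lower_bound")

    x = np.log10(glucose)
    # perfect separation: every outcome below some boundary is 0, above is 1
    max_x_fail = x[outcome == 0].max()
    min_x_success = x[outcome == 1].min()
    if min_x_success > max_x_fail:
        boundary = 10.0 ** (0.5 * (max_x_fail + min_x_success))
        return MinGlucoseResult(float(boundary), target_p, "separation")

    exog = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = sm.Logit(outcome, exog).fit(disp=0, maxiter=200)
    intercept, slope = result.params
    if slope <= 0:
        raise ValueError("fitted germination probability not increasing in glucose")
    logit_target = math.log(target_p / (1.0 - target_p))
    x_target = (logit_target - intercept) / slope
    conc = 10.0**x_target
    flag = "fitted" if x.min() <= x_target <= x.max() else "extrapolated"
    return MinGlucoseResult(float(conc), target_p, flag, float(slope), float(intercept))


# --------------------------------------------------------------------------
# marker-marker association


@dataclass(frozen=True)
class AssociationResult:
    pearson_r: float
    p_value: float
    slope: float
    intercept: float
    n: int


def pearson_association(x, y) -> AssociationResult:
    """Pearson correlation with two-sided p-value plus the OLS line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D with equal length")
    if x.size < 3:
        raise ValueError("need n >= 3 for a defined p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    reg = stats.linregress(x, y)
    return AssociationResult(float(r), float(p), float(reg.slope), float(reg.intercept), x.size)
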