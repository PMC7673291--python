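"""Generative germination response shared by the data generator and the
threshold-death simulator.

A spore bag's probability of germinating is modelled as logistic in
log-glucose with a half-maximal concentration (c50) that decreases with the
bag's gene-expressing capacity:

    p(c; x) = floor + (ceiling - floor) / (1 + (c50(x) / c) ** hill)
    c50(x)  = c50_ref * (x / capacity_ref) ** (-coupling)

so more capable bags need less glucose. The coupling is linear in log-log
space; with coupling > 0 the response is monotone nondecreasing in both
glucose and capacity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GerminationResponse"]


@dataclass(frozen=True)
class GerminationResponse:
    """Per-bag germination probability as a function of glucose and capacity.

    Parameters
    ----------
    c50_ref : float
        Half-maximal glucose concentration (% w/v) for a bag at the
        reference capacity.
    hill_slope : float
        Steepness of the per-bag response in glucose. The single-bag
        response is a sharp, step-like sigmoid.
    floor_prob, ceiling_prob : float
        Germination probability far below / far above the per-bag c50.
    capacity_coupling : float
        How many decades log10(c50) falls per decade of capacity.
    capacity_ref : float
        Capacity (a.u.) at which c50 equals ``c50_ref``.
    """

    c50_ref: float = 0.003
    hill_slope: float = 14.0
    floor_prob: float = 0.10
    ceiling_prob: float = 1.0
    capacity_coupling: float = 1.9
    capacity_ref: float = 1000.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.floor_prob <= 1.0 and 0.0 <= self.ceiling_prob <= 1.0):
            raise ValueError("floor_prob and ceiling_prob must lie in [0, 1]")
        if self.ceiling_prob < self.floor_prob:
            raise ValueError("ceiling_prob must be >= floor_prob")
        if self.c50_ref <= 0 or self.hill_slope <= 0 or self.capacity_ref <= 0:
            raise ValueError("c50_ref, hill_slope and capacity_ref must be positive")

    def c50(self, capacity):
        """Half-maximal glucose (% w/v) for bags of the given capacity."""
        capacity = np.asarray(capacity, dtype=float)
        if np.any(capacity <= 0):
            raise ValueError("capacity must be positive")
        return self.c50_ref * (capacity / self.capacity_ref) ** (-self.capacity_coupling)

    def prob(self, glucose_pct, capacity):
        """Germination probability at ``glucose_pct`` for the given capacity."""
        glucose = np.asarray(glucose_pct, dtype=float)
        if np.any(glucose <= 0):
            raise ValueError("glucose concentrations must be positive")
        # work in log space to keep the steep hill numerically stable
        log_ratio = np.log(self.c50(capacity)) - np.log(glucose)
        z = np.clip(self.hill_slope * log_ratio, -700.0, 700.0)
        logistic = 1.0 / (1.0 + np.exp(z))
        return self.floor_prob + (self.ceiling_prob - self.floor_prob) * logistic

    def min_glucose(self, capacity, target_p: float = 0.99):
        """Closed-form glucose concentration at which ``prob`` equals
        ``target_p`` for a bag of the given capacity.

        Returns ``nan`` where the target is unreachable (outside
        (floor, ceiling)).
        """
        capacity = np.asarray(capacity, dtype=float)
        span = self.ceiling_prob - self.floor_prob
        frac = (target_p - self.floor_prob) / span if span > 0 else np.nan
        c50 = self.c50(capacity)
        with np.errstate(divide="ignore", invalid="ignore"):
            odds = frac / (1.0 - frac)
            result = c50 * odds ** (1.0 / self.hill_slope)
        bad = not (0.0 < frac < 1.0) if np.isscalar(frac) else False
        if bad:
            return np.full_like(c50, np.nan)
        return result
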