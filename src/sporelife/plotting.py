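"""Matplotlib views of the main objects: landscape heat map, dose-response
curve, trace panels and survival curves."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_dose_response", "plot_landscape", "plot_survival", "plot_traces"]


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_landscape(grid, ax=None, cmap="viridis"):
    """Heat map of germination probability over glucose x marker bins."""
    ax = _axes(ax)
    masked = np.ma.masked_invalid(grid.prob)
    mesh = ax.pcolormesh(
        grid.bin_edges,
        np.arange(grid.glucose_levels.size + 1),
        masked,
        cmap=cmap,
        vmin=0.0,
        vmax=1.0,
    )
    ax.set_yticks(np.arange(grid.glucose_levels.size) + 0.5)
    ax.set_yticklabels([f"{g:g}" for g in grid.glucose_levels])
    ax.set_xlabel(f"{grid.marker_name} (a.u.)")
    ax.set_ylabel("glucose (% w/v)")
    ax.figure.colorbar(mesh, ax=ax, label="germination probability")
    return ax


def plot_dose_response(results, glucose, fraction, ax=None):
    ax = _axes(ax)
    ax.semilogx(glucose, fraction, "rs", label="observed")
    grid = np.geomspace(min(glucose), max(glucose), 200)
    ax.semilogx(grid, results.predict(grid), "k-", label="4PL fit")
    ax.axvline(results.c50, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("glucose (% w/v)")
    ax.set_ylabel("fraction germinated")
    ax.legend()
    return ax


def plot_traces(traces, ax=None, color="tab:blue", alpha=0.5):
    ax = _axes(ax)
    for tr in traces:
        ax.plot(tr.times_h, tr.fold_change, color=color, alpha=alpha, lw=0.8)
    ax.set_xlabel("time after glucose (h)")
    ax.set_ylabel("fold change in RNAP II level")
    return ax


def plot_survival(sample_days, survival, ax=None, **kwargs):
    ax = _axes(ax)
    ax.plot(sample_days, np.asarray(survival) * 100.0, marker="o", **kwargs)
    ax.set_xlabel("age (days)")
    ax.set_ylabel("% spore bags alive")
    ax.set_ylim(0, 105)
    return ax
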