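"""Figure helpers: per-subject curve spaghetti and F-vs-critical panels."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .flm import FLMResult
from .fourier import CurveMatrix

_HOUR_TICKS = np.arange(0, 25, 4)


def _clock_axis(ax) -> None:
    ax.set_xticks(_HOUR_TICKS * 60)
    ax.set_xticklabels([f"{h:02d}:00" for h in _HOUR_TICKS])
    ax.set_xlim(0, 1440)
    ax.set_xlabel("clock time")


def plot_diurnal_curves(curves: CurveMatrix, path=None, title="Smoothed 24-h activity"):
    """Per-subject smoothed curves with the cohort grand mean overlaid."""
    fig, ax = plt.subplots(figsize=(9, 4.5))
    vals = curves.clipped()
    for row in vals:
        ax.plot(curves.grid, row, color="grey", alpha=0.35, lw=0.7)
    ax.plot(curves.grid, vals.mean(axis=0), color="black", lw=2.2, label="cohort mean")
    _clock_axis(ax)
    ax.set_ylabel("activity (counts/epoch)")
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_flm_panel(
    curves: CurveMatrix, result: FLMResult, group_mask=None, path=None, title=""
):
    """Two-panel display: mean curves (by group if given) above the observed
    F statistic against the pointwise permutation critical curve."""
    fig, (ax0, ax1) = plt.subplots(2, 1, figsize=(9, 6.5), sharex=True)
    vals = curves.clipped()
    if group_mask is not None:
        group_mask = np.asarray(group_mask, dtype=bool)
        ax0.plot(curves.grid, vals[group_mask].mean(axis=0), lw=1.8, label="group 1")
        ax0.plot(curves.grid, vals[~group_mask].mean(axis=0), lw=1.8, label="group 0")
        ax0.legend(frameon=False)
    else:
        ax0.plot(curves.grid, vals.mean(axis=0), color="black", lw=1.8)
    ax0.set_ylabel("activity (counts/epoch)")
    ax0.set_title(title or f"FLM: {result.covariate}")

    ax1.plot(result.grid, result.observed_F, color="crimson", lw=1.6, label="observed F")
    ax1.plot(
        result.grid,
        result.critical_curve,
        color="steelblue",
        ls=":",
        lw=1.6,
        label=f"pointwise critical ({1 - result.alpha:.0%})",
    )
    sig = result.significant_mask()
    if sig.any():
        ax1.fill_between(
            result.grid, 0, np.nanmax(result.observed_F[np.isfinite(result.observed_F)]),
            where=sig, color="crimson", alpha=0.08,
        )
    ax1.set_ylabel("F statistic")
    ax1.legend(frameon=False)
    _clock_axis(ax1)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
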