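"""Smooth 24-h periodic activity functions via truncated Fourier series.

Each subject's multi-day epoch record is collapsed to a per-clock-minute
average profile, then projected onto the periodic basis
{1, cos(2*pi*k*t/24), sin(2*pi*k*t/24)}, k = 1..K, by ordinary least
squares on the non-missing minutes. The fit is a plain linear
projection: no roughness penalty, missing minutes are simply excluded
(the basis interpolates through gaps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._clock import MINUTES_PER_DAY
from .io import ActigraphyError, EpochSeries

PERIOD_HOURS = 24.0
DEFAULT_N_HARMONICS = 9


@dataclass
class DiurnalProfile:
    """Across-day average activity at each clock minute for one subject."""

    subject_id: str
    minute_grid: np.ndarray
    mean_counts: np.ndarray  # NaN where no day contributed
    n_days_contributing: np.ndarray

    def __post_init__(self) -> None:
        self.minute_grid = np.asarray(self.minute_grid)
        self.mean_counts = np.asarray(self.mean_counts, dtype=float)
        self.n_days_contributing = np.asarray(self.n_days_contributing, dtype=np.int64)
        observed = self.mean_counts[self.n_days_contributing > 0]
        if observed.size and np.nanmin(observed) < 0:
            raise ActigraphyError("negative mean counts in profile")

    @property
    def observed(self) -> np.ndarray:
        return self.n_days_contributing > 0


@dataclass
class FourierCurve:
    """A periodic smooth activity function in Fourier coefficients."""

    subject_id: str
    intercept: float
    cosine_coefs: np.ndarray
    sine_coefs: np.ndarray
    rss: float = np.nan
    n_obs: int = 0

    def __post_init__(self) -> None:
        self.cosine_coefs = np.asarray(self.cosine_coefs, dtype=float)
        self.sine_coefs = np.asarray(self.sine_coefs, dtype=float)
        coefs = np.r_[self.intercept, self.cosine_coefs, self.sine_coefs]
        if not np.all(np.isfinite(coefs)):
            raise ActigraphyError("non-finite Fourier coefficients")

    @property
    def n_harmonics(self) -> int:
        return int(self.cosine_coefs.size)

    def evaluate(self, minute_of_day) -> np.ndarray:
        """Evaluate at clock minutes; exactly 24-h periodic."""
        t = np.asarray(minute_of_day, dtype=float) / 60.0
        k = np.arange(1, self.n_harmonics + 1)
        ang = 2.0 * np.pi * np.outer(t, k) / PERIOD_HOURS
        return (
            self.intercept
            + np.cos(ang) @ self.cosine_coefs
            + np.sin(ang) @ self.sine_coefs
        )

    def coefficients(self) -> np.ndarray:
        """(intercept, cos_1..K, sin_1..K) as one vector."""
        return np.r_[self.intercept, self.cosine_coefs, self.sine_coefs]


@dataclass
class CurveMatrix:
    """Smoothed curves for a whole cohort on a common clock grid."""

    subject_ids: list
    grid: np.ndarray  # clock minutes
    values: np.ndarray  # subjects x grid, raw evaluations (may dip < 0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), self.grid.size):
            raise ActigraphyError("curve matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ActigraphyError("missing entries in curve matrix")

    def clipped(self) -> np.ndarray:
        """Nonnegative copy for plotting only, never for inference."""
        return np.clip(self.values, 0.0, None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.grid)


def average_daily_profile(series: EpochSeries) -> DiurnalProfile:
    """Mean of non-missing counts at each clock minute across recorded days."""
    if series.missing.all():
        raise ActigraphyError(f"{series.subject_id}: all epochs missing")
    minute = series.minute_of_day
    counts = series.masked_counts()
    grid = np.arange(0, MINUTES_PER_DAY, series.epoch_minutes)
    mean = np.full(grid.size, np.nan)
    n_days = np.zeros(grid.size, dtype=np.int64)
    order = np.argsort(minute, kind="stable")
    bounds = np.searchsorted(minute[order], grid)
    for i, g in enumerate(grid):
        lo = bounds[i]
        hi = bounds[i + 1] if i + 1 < grid.size else minute.size
        vals = counts[order[lo:hi]]
        vals = vals[~np.isnan(vals)]
        n_days[i] = vals.size
        if vals.size:
            mean[i] = vals.mean()
    return DiurnalProfile(series.subject_id, grid, mean, n_days)


def fourier_design(minute_of_day, n_harmonics: int) -> np.ndarray:
    t = np.asarray(minute_of_day, dtype=float) / 60.0
    k = np.arange(1, n_harmonics + 1)
    ang = 2.0 * np.pi * np.outer(t, k) / PERIOD_HOURS
    return np.column_stack([np.ones(t.size), np.cos(ang), np.sin(ang)])


def fourier_fit(profile: DiurnalProfile, n_harmonics: int = DEFAULT_N_HARMONICS) -> FourierCurve:
    """Least-squares projection of a diurnal profile onto K harmonics.

    Fitted on non-missing minutes only; requires at least 2K+1 of them.
    """
    if n_harmonics < 1:
        raise ActigraphyError("n_harmonics must be >= 1")
    obs = profile.observed & np.isfinite(profile.mean_counts)
    n_coef = 2 * n_harmonics + 1
    if obs.sum() < n_coef:
        raise ActigraphyError(
            f"{profile.subject_id}: {int(obs.sum())} observed minutes < {n_coef} coefficients"
        )
    X = fourier_design(profile.minute_grid[obs], n_harmonics)
    y = profile.mean_counts[obs]
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    return FourierCurve(
        subject_id=profile.subject_id,
        intercept=float(beta[0]),
        cosine_coefs=beta[1 : n_harmonics + 1],
        sine_coefs=beta[n_harmonics + 1 :],
        rss=rss,
        n_obs=int(obs.sum()),
    )


def evaluate_curves(curves: list, grid=None) -> CurveMatrix:
    """Evaluate a cohort's curves on a common clock grid (default 1440 min)."""
    if grid is None:
        grid = np.arange(MINUTES_PER_DAY)
    grid = np.asarray(grid)
    values = np.vstack([c.evaluate(grid) for c in curves])
    return CurveMatrix([c.subject_id for c in curves], grid, values)


def smooth_cohort(cohort, n_harmonics: int = DEFAULT_N_HARMONICS, grid=None):
    """Cohort -> (list of FourierCurve, CurveMatrix), ordered as metadata."""
    curves = []
    for sid in cohort.subjects["id"]:
        prof = average_daily_profile(cohort.series[sid])
        curves.append(fourier_fit(prof, n_harmonics))
    return curves, evaluate_curves(curves, grid)
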