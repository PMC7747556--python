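"""Pointwise functional linear modeling of 24-h activity curves.

At every clock grid point the smoothed activity values are regressed on
a subject-level design (intercept plus covariates); an F statistic for
the covariate under test is computed pointwise, and its null
distribution is obtained by permuting the subject-to-covariate
assignment while the curves stay fixed. The critical-value curve is the
empirical (1 - alpha) quantile of the permutation F values at each
point; time points where the observed F exceeds it differ significantly
between covariate levels (or along the covariate, for continuous
predictors).

The permutation unit is always the whole subject curve — exchangeable
under the null of no covariate effect; within-curve or within-day
shuffles would break the temporal dependence structure and are never
used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._clock import MINUTES_PER_DAY, fmt_clock
from .fourier import CurveMatrix


class DesignError(ValueError):
    pass


@dataclass
class RegressionDesign:
    """Subject-level design matrix with the columns under test marked."""

    covariate_names: list
    matrix: np.ndarray  # n_subjects x p, first column typically intercept
    test_columns: list  # indices of the q columns whose effect is tested

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise DesignError("design matrix must be 2-d")
        n, p = self.matrix.shape
        if len(self.covariate_names) != p:
            raise DesignError("one name per design column required")
        if not self.test_columns:
            raise DesignError("no columns under test")
        if np.linalg.matrix_rank(self.matrix) < p:
            suspects = [
                self.covariate_names[j]
                for j in range(p)
                if np.linalg.matrix_rank(np.delete(self.matrix, j, axis=1)) == np.linalg.matrix_rank(self.matrix)
            ]
            raise DesignError(f"rank-deficient design; collinear columns: {suspects}")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def reduced_matrix(self) -> np.ndarray:
        return np.delete(self.matrix, self.test_columns, axis=1)

    @classmethod
    def from_metadata(
        cls, metadata: pd.DataFrame, covariate: str, adjust_for: tuple = ()
    ) -> "RegressionDesign":
        """Build an intercept + covariate design from a metadata table.

        ``sex`` becomes a male dummy and ``day_type`` a weekend dummy;
        ``age`` and ``mass`` enter as given (the F statistic is invariant
        to their scaling). ``adjust_for`` appends nuisance covariates
        whose effect is not tested.
        """
        def encode(name: str) -> np.ndarray:
            if name == "sex":
                return (metadata["sex"].to_numpy() == "M").astype(float)
            if name == "day_type":
                return (metadata["day_type"].to_numpy() == "weekend").astype(float)
            return metadata[name].to_numpy(dtype=float)

        cols = [np.ones(len(metadata))]
        names = ["intercept"]
        for name in (covariate, *adjust_for):
            cols.append(encode(name))
            names.append(name)
        return cls(names, np.column_stack(cols), test_columns=[1])


@dataclass
class FLMResult:
    """Observed F curve, permutation critical curve and pointwise p-curve."""

    grid: np.ndarray  # clock minutes
    observed_F: np.ndarray
    critical_curve: np.ndarray
    pointwise_p: np.ndarray
    n_permutations: int
    alpha: float
    seed: int | None
    covariate: str = ""
    significant_intervals: list = field(default_factory=list)

    def significant_mask(self) -> np.ndarray:
        """Grid points where the observed F exceeds the critical curve."""
        return self.observed_F > self.critical_curve

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "minute": self.grid,
                "observed_F": self.observed_F,
                "critical": self.critical_curve,
                "p": self.pointwise_p,
                "significant": self.significant_mask().astype(int),
            }
        )


def _sse(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Columnwise residual sum of squares of OLS of Y (n x G) on X (n x p)."""
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return np.einsum("ij,ij->j", resid, resid)


def pointwise_F(curves: CurveMatrix, design: RegressionDesign) -> np.ndarray:
    """F statistic for the tested covariate at every grid point.

    F(t) = [(SSE_reduced - SSE_full)/q] / [SSE_full/(n - p)]. For a
    single two-level factor with intercept this is the one-way ANOVA F.
    Points with zero full-model residual variance report +inf.
    """
    Y = curves.values  # n_subjects x G
    n, p = design.matrix.shape
    if n <= p:
        raise DesignError(f"need more subjects ({n}) than design columns ({p})")
    if curves.values.shape[0] != n:
        raise DesignError("curve matrix rows do not match design rows")
    q = len(design.test_columns)
    sse_full = _sse(design.matrix, Y)
    sse_red = _sse(design.reduced_matrix, Y)
    # an SSE at floating-noise level relative to the response scale is zero
    tol = (np.einsum("ij,ij->j", Y, Y) + 1e-300) * 1e-20
    sse_full = np.where(sse_full < tol, 0.0, sse_full)
    sse_red = np.where(sse_red < tol, 0.0, sse_red)
    num = np.where(sse_red - sse_full < tol, 0.0, sse_red - sse_full) / q
    with np.errstate(divide="ignore", invalid="ignore"):
        F = num / (sse_full / (n - p))
    zero_var = sse_full <= 0
    if zero_var.any():
        warnings.warn(
            f"zero residual variance at {int(zero_var.sum())} grid points; F set to +inf",
            RuntimeWarning,
            stacklevel=2,
        )
        F = np.where(zero_var & (num > 0), np.inf, F)
        F = np.where(zero_var & (num <= 0), 0.0, F)
    return F


def _check_factor_levels(design: RegressionDesign) -> None:
    for j in design.test_columns:
        col = design.matrix[:, j]
        levels, counts = np.unique(col, return_counts=True)
        if levels.size <= 2 and counts.min() < 2:
            raise DesignError(
                f"factor column {design.covariate_names[j]!r} has a level with < 2 subjects"
            )


def permutation_test(
    curves: CurveMatrix,
    design: RegressionDesign,
    n_permutations: int = 500,
    alpha: float = 0.05,
    seed: int | None = None,
    permute: str = "columns",
) -> FLMResult:
    """Pointwise permutation F-test of one covariate on activity curves.

    Each permutation shuffles the subject-to-covariate assignment (rows
    of the tested columns for ``permute='columns'``, all non-intercept
    rows jointly for ``permute='full'``) while the curves stay fixed.
    The observed assignment is always included as the first permutation,
    so the pointwise p-curve — the proportion of permutation F values at
    or above the observed one — is bounded below by 1/n_permutations and
    the test is exact. The critical curve is the empirical (1 - alpha)
    order-statistic quantile of the permutation F values at each grid
    point.
    """
    if n_permutations < 1:
        raise DesignError("n_permutations must be >= 1")
    if not 0 < alpha < 1:
        raise DesignError("alpha must be in (0, 1)")
    if permute not in {"columns", "full"}:
        raise DesignError(f"unknown permutation mode {permute!r}")
    _check_factor_levels(design)

    observed = pointwise_F(curves, design)
    rng = np.random.default_rng(seed)
    n = design.n_subjects
    perm_F = np.empty((n_permutations, curves.grid.size))
    shuffle_cols = (
        design.test_columns
        if permute == "columns"
        else [j for j in range(design.matrix.shape[1]) if design.covariate_names[j] != "intercept"]
    )
    perm_F[0] = observed  # identity assignment is always a member
    for b in range(1, n_permutations):
        order = rng.permutation(n)
        M = design.matrix.copy()
        M[:, shuffle_cols] = M[np.ix_(order, shuffle_cols)]
        perm_design = RegressionDesign.__new__(RegressionDesign)
        perm_design.covariate_names = design.covariate_names
        perm_design.matrix = M
        perm_design.test_columns = design.test_columns
        perm_F[b] = pointwise_F(curves, perm_design)

    k = int(np.ceil((1.0 - alpha) * n_permutations)) - 1
    critical = np.sort(perm_F, axis=0)[k]
    pointwise_p = np.mean(perm_F >= observed[None, :], axis=0)

    result = FLMResult(
        grid=curves.grid,
        observed_F=observed,
        critical_curve=critical,
        pointwise_p=pointwise_p,
        n_permutations=n_permutations,
        alpha=alpha,
        seed=seed,
        covariate=", ".join(design.covariate_names[j] for j in design.test_columns),
    )
    result.significant_intervals = significant_intervals(result)
    return result


def significant_intervals(result: FLMResult) -> list:
    """Maximal runs of significant grid points as wrapped clock intervals.

    Returns dicts with start/end clock strings, start/end minutes
    (half-open, end may exceed 1440 when the run wraps midnight) and
    duration in minutes.
    """
    sig = result.significant_mask()
    G = sig.size
    if not sig.any():
        return []
    grid = np.asarray(result.grid)
    step = int(grid[1] - grid[0]) if G > 1 else MINUTES_PER_DAY
    if sig.all():
        return [_interval(int(grid[0]), MINUTES_PER_DAY)]

    # rotate so the scan starts at a non-significant point, then wraps free
    start0 = int(np.argmin(sig))
    rot = np.roll(sig, -start0)
    intervals = []
    b = 0
    while b < G:
        if not rot[b]:
            b += 1
            continue
        e = b
        while e < G and rot[e]:
            e += 1
        start_min = int(grid[(b + start0) % G])
        intervals.append(_interval(start_min, (e - b) * step))
        b = e
    intervals.sort(key=lambda iv: iv["start_minute"])
    return intervals


def _interval(start_min: int, duration_min: int) -> dict:
    end = start_min + duration_min
    return {
        "start_minute": start_min,
        "end_minute": end,
        "duration_minutes": duration_min,
        "start_clock": fmt_clock(start_min),
        "end_clock": fmt_clock(end % MINUTES_PER_DAY),
    }


def intervals_frame(result: FLMResult) -> pd.DataFrame:
    cols = ["start_clock", "end_clock", "start_minute", "end_minute", "duration_minutes"]
    return pd.DataFrame(result.significant_intervals, columns=cols)
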