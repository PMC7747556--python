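"""Synthetic dog-actigraphy cohorts with known ground truth.

The generator emulates a companion-dog cohort wearing collar-mounted
accelerometers recording 1-min epoch counts for two weeks: a bimodal
diurnal mean pattern (morning and evening peaks, midday trough, deepest
level overnight), per-dog covariates (age, sex, body mass), owner-diary
night windows, weekday/weekend daytime modulation, a per-dog random
level, and overdispersed (negative-binomial) count noise. Covariate
effects are injected multiplicatively on the log rate within configured
clock windows, so both downstream inference stages — the pointwise
functional F-test and the day/night log-activity mixed model — see a
correctly specified signal with known truth.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._clock import MINUTES_PER_DAY, fmt_clock, hours_to_minutes, in_window
from .io import EpochSeries, NightWindow, day_type_of, write_diary_csv, write_epoch_csv

#: Fixed covariate centres used when applying effects, so the overall
#: count scale does not drift with cohort composition (midpoints of the
#: configured age and mass ranges).
AGE_CENTER = 5.5
MASS_CENTER = 24.05


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class CovariateEffect:
    """A time-localized multiplicative covariate effect on the log rate.

    ``amplitude`` is the log-rate slope per covariate unit (years, kg, or
    a 0/1 dummy for sex=male and day_type=weekend), applied inside each
    clock-hour window in ``windows`` and exactly zero outside. A custom
    24-h-periodic ``curve`` (clock hour -> slope) may replace the
    box-shaped default; it is still zeroed outside the windows so the
    zero-outside-window invariant holds by construction.

    ``shape='taper'`` replaces the box with a raised-cosine edge taper of
    ``taper_minutes`` inside each window (full amplitude in the middle,
    smooth ramps to zero at the edges). Biological effects do not switch
    on discontinuously, and a discontinuous effect pushed through a
    truncated Fourier smoother rings far outside its window (Gibbs);
    the taper keeps the injected signal representable.
    """

    covariate: str  # age | sex | mass | day_type
    amplitude: float
    windows: tuple = ((0.0, 24.0),)
    shape: str = "box"  # box | taper
    taper_minutes: int = 45
    curve: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.covariate not in {"age", "sex", "mass", "day_type"}:
            raise SimulationError(f"unknown covariate {self.covariate!r}")
        if not np.isfinite(self.amplitude):
            raise SimulationError("effect amplitude must be finite")
        if self.shape not in {"box", "taper"}:
            raise SimulationError(f"unknown effect shape {self.shape!r}")

    def slope(self, minute_of_day: np.ndarray) -> np.ndarray:
        """Log-rate slope per covariate unit at each clock minute."""
        m = np.asarray(minute_of_day)
        weight = np.zeros(m.shape, dtype=float)
        for lo, hi in self.windows:
            lo_m, hi_m = hours_to_minutes(lo), hours_to_minutes(hi)
            inside = in_window(m, lo_m, hi_m)
            if self.shape == "box":
                weight = np.where(inside, 1.0, weight)
            else:
                length = (hi_m - lo_m) % MINUTES_PER_DAY
                depth = (m - lo_m) % MINUTES_PER_DAY  # minutes into the window
                edge = np.minimum(depth, length - depth - 1)
                ramp = np.clip(edge / max(self.taper_minutes, 1), 0.0, 1.0)
                w = 0.5 * (1.0 - np.cos(np.pi * ramp))
                weight = np.where(inside, np.maximum(weight, w), weight)
        if self.curve is None:
            vals = self.amplitude * weight
        else:
            vals = np.asarray(self.curve(m / 60.0), dtype=float) * (weight > 0)
        return vals


def default_effects() -> tuple:
    """Default covariate effects: younger dogs more active in
    both activity peaks, females more active in the evening, lighter dogs
    slightly more active just after midnight."""
    return (
        CovariateEffect("age", -0.05, windows=((7.0, 10.0), (17.5, 21.0))),
        CovariateEffect("sex", -0.15, windows=((18.0, 22.0),)),
        CovariateEffect("mass", -0.004, windows=((0.0, 1.0),)),
    )


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for a simulated cohort.

    Defaults describe a typical two-week companion-dog cohort: 42 dogs,
    14 days of 1-min epochs, activity peaks near 07:00 and 19:00 with a
    midday trough above the overnight level, ages 2-9 y, masses
    2.7-45.4 kg, balanced sex, bedtimes 22:00-23:00 and waketimes
    06:00-08:00.

    Between-dog variability: a scalar random level
    (``random_intercept_sd``, log scale) and a smooth random *shape*
    deviation — independent Fourier harmonics on the log rate with
    per-harmonic SD ``shape_sd`` — so dogs differ in their activity
    pattern across the day, not merely in overall amount. A per-dog
    nighttime restlessness level (``night_level_sd``, log scale, applied
    inside the dog's own night windows) captures how much dogs differ in
    overnight movement.
    """

    n_subjects: int = 42
    n_days: int = 14
    epoch_minutes: int = 1
    peak_times: tuple = (7.0, 19.0)  # clock hours
    peak_widths: tuple = (1.5, 1.5)  # hours (circular-Gaussian SD)
    peak_heights: tuple = (180.0, 180.0)  # counts/epoch above baseline
    baseline_day: float = 60.0
    baseline_night: float = 8.0
    night_span: tuple = (22.0, 7.0)  # template baseline step only
    weekend_day_multiplier: float = 1.25
    effect_spec: tuple = field(default_factory=default_effects)
    random_intercept_sd: float = 0.2
    shape_sd: float = 0.15  # per-harmonic SD of the per-dog log-rate deviation
    shape_harmonics: int = 9
    night_level_sd: float = 0.5  # per-dog nighttime restlessness (log scale)
    dispersion: float = 2.0  # NB size; var = mu + mu^2/dispersion
    gap_rate: float = 0.0
    age_range: tuple = (2.0, 9.0)
    mass_range: tuple = (2.7, 45.4)
    bedtime_range: tuple = (22.0, 23.0)
    waketime_range: tuple = (6.0, 8.0)
    night_jitter_minutes: int = 30
    start_date: str = "2020-01-06"  # a Monday: 14 days = 10 weekday + 4 weekend
    seed: int = 0

    def __post_init__(self) -> None:
        numeric = [
            *self.peak_times, *self.peak_widths, *self.peak_heights,
            self.baseline_day, self.baseline_night, self.weekend_day_multiplier,
            self.random_intercept_sd, self.shape_sd, self.night_level_sd,
            self.dispersion, self.gap_rate,
        ]
        if not np.all(np.isfinite(numeric)):
            raise SimulationError("non-finite configuration parameter")
        if self.shape_sd < 0 or self.shape_harmonics < 0 or self.night_level_sd < 0:
            raise SimulationError("variability parameters must be nonnegative")
        if self.n_subjects < 2:
            raise SimulationError("need at least 2 subjects")
        if self.n_days < 1:
            raise SimulationError("need at least 1 day")
        if MINUTES_PER_DAY % self.epoch_minutes != 0:
            raise SimulationError("epoch_minutes must divide 1440")
        if min(self.peak_heights) < 0 or self.baseline_day < 0 or self.baseline_night < 0:
            raise SimulationError("rates must be nonnegative")
        if min(self.peak_widths) <= 0:
            raise SimulationError("peak widths must be positive")
        if self.dispersion <= 0:
            raise SimulationError("dispersion must be positive")
        if not 0 <= self.gap_rate <= 1:
            raise SimulationError("gap_rate must be in [0, 1]")

    def without_effects(self) -> "SimConfig":
        """Copy with every covariate effect removed (null cohort)."""
        return replace(self, effect_spec=())


@dataclass
class SimulatedCohort:
    """Simulator output: epoch series, latent truth table, night diary."""

    series: list
    truth: pd.DataFrame
    diary: dict  # id -> list of NightWindow
    config: SimConfig

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for s in self.series:
            write_epoch_csv(s, out_dir / f"epochs_{s.subject_id}.csv")
        meta = self.truth[["id", "age", "sex", "mass"]]
        meta.to_csv(out_dir / "metadata.csv", index=False)
        self.truth.to_csv(out_dir / "truth.csv", index=False)
        write_diary_csv(self.diary, out_dir / "diary.csv")


# ---------------------------------------------------------------------------
# the diurnal mean template
# ---------------------------------------------------------------------------

def diurnal_template(config: SimConfig, t_hours) -> np.ndarray:
    """Population mean activity rate (counts/epoch) at clock time ``t``.

    Sum of circular-Gaussian (von Mises) bumps at the configured peak
    times over a day/night step baseline; exactly 24-h periodic and
    nonnegative.
    """
    t = np.asarray(t_hours, dtype=float)
    if not np.all(np.isfinite(t)):
        raise SimulationError("non-finite evaluation time")
    minute = np.round(t * 60.0).astype(np.int64) % MINUTES_PER_DAY
    night = in_window(
        minute, hours_to_minutes(config.night_span[0]), hours_to_minutes(config.night_span[1])
    )
    rate = np.where(night, config.baseline_night, config.baseline_day).astype(float)
    for mu, width, height in zip(config.peak_times, config.peak_widths, config.peak_heights):
        sigma_rad = width * 2.0 * np.pi / 24.0
        kappa = 1.0 / sigma_rad**2
        ang = 2.0 * np.pi * (t - mu) / 24.0
        rate = rate + height * np.exp(kappa * (np.cos(ang) - 1.0))
    return rate


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _draw_subjects(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_subjects
    sex = np.array(["F", "M"] * ((n + 1) // 2))[:n]
    sex = rng.permutation(sex)
    return pd.DataFrame(
        {
            "id": [f"dog{i + 1:03d}" for i in range(n)],
            "age": np.round(rng.uniform(*config.age_range, size=n), 1),
            "sex": sex,
            "mass": np.round(rng.uniform(*config.mass_range, size=n), 1),
            "random_intercept": rng.normal(0.0, config.random_intercept_sd, size=n),
            "bedtime": [
                fmt_clock(hours_to_minutes(b)) for b in rng.uniform(*config.bedtime_range, size=n)
            ],
            "waketime": [
                fmt_clock(hours_to_minutes(w)) for w in rng.uniform(*config.waketime_range, size=n)
            ],
        }
    )


def _subject_nights(
    config: SimConfig, row: pd.Series, start_date: _dt.date, rng: np.random.Generator
) -> list:
    """Jittered diary nights for one subject, starting the evening before
    recording so the first morning is covered."""
    from ._clock import parse_clock

    base_bed = parse_clock(row["bedtime"])
    base_wake = parse_clock(row["waketime"])
    j = config.night_jitter_minutes
    nights = []
    for d in range(-1, config.n_days):
        date = start_date + _dt.timedelta(days=d)
        bed = (base_bed + int(rng.integers(-j, j + 1))) % MINUTES_PER_DAY
        wake = (base_wake + int(rng.integers(-j, j + 1))) % MINUTES_PER_DAY
        nights.append(NightWindow(row["id"], date, bed, wake))
    return nights


def latent_rate(
    config: SimConfig,
    row: pd.Series,
    nights: Sequence[NightWindow],
    start_date: _dt.date,
    shape_coefs: np.ndarray | None = None,
    night_level: float = 0.0,
) -> np.ndarray:
    """Per-epoch expected count for one subject over the full record.

    template with the subject's actual (diary) nights as the baseline
    step, times the weekend daytime multiplier, times
    exp(random intercept + smooth per-dog shape deviation + sum of
    windowed covariate effects). ``shape_coefs`` is a (2, K) array of
    cosine/sine harmonic coefficients of the log-rate deviation;
    ``night_level`` is the dog's log-scale restlessness offset applied
    inside its night windows.
    """
    eppd = MINUTES_PER_DAY // config.epoch_minutes
    n_epochs = config.n_days * eppd
    minute = (np.arange(n_epochs) * config.epoch_minutes) % MINUTES_PER_DAY
    abs_minute = np.arange(n_epochs) * config.epoch_minutes
    t_hours = minute / 60.0

    # night mask from the subject's own diary windows
    night = np.zeros(n_epochs, dtype=bool)
    for w in nights:
        day_offset = (w.date - start_date).days
        start = day_offset * MINUTES_PER_DAY + w.bedtime
        end = start + ((w.waketime - w.bedtime) % MINUTES_PER_DAY)
        night |= (abs_minute >= start) & (abs_minute < end)

    rate = np.where(night, config.baseline_night, config.baseline_day).astype(float)
    for mu, width, height in zip(config.peak_times, config.peak_widths, config.peak_heights):
        sigma_rad = width * 2.0 * np.pi / 24.0
        kappa = 1.0 / sigma_rad**2
        ang = 2.0 * np.pi * (t_hours - mu) / 24.0
        rate = rate + height * np.exp(kappa * (np.cos(ang) - 1.0))

    dates = np.array(
        [start_date + _dt.timedelta(days=int(d)) for d in abs_minute // MINUTES_PER_DAY]
    )
    weekend = np.array([day_type_of(d) == "weekend" for d in dates])
    rate = np.where(weekend & ~night, rate * config.weekend_day_multiplier, rate)

    covariate_values = {
        "age": float(row["age"]) - AGE_CENTER,
        "mass": float(row["mass"]) - MASS_CENTER,
        "sex": 1.0 if row["sex"] == "M" else 0.0,
    }
    log_eff = np.full(n_epochs, float(row["random_intercept"]))
    log_eff = log_eff + night_level * night
    if shape_coefs is not None and shape_coefs.size:
        k = np.arange(1, shape_coefs.shape[1] + 1)
        ang = 2.0 * np.pi * np.outer(t_hours, k) / 24.0
        log_eff = log_eff + np.cos(ang) @ shape_coefs[0] + np.sin(ang) @ shape_coefs[1]
    for eff in config.effect_spec:
        if eff.covariate == "day_type":
            x = weekend.astype(float)
        else:
            x = covariate_values[eff.covariate]
        log_eff = log_eff + eff.slope(minute) * x
    return rate * np.exp(log_eff)


def generate_cohort(config: SimConfig) -> SimulatedCohort:
    """Simulate a full cohort; a pure function of (config, seed)."""
    rng = np.random.default_rng(config.seed)
    subjects = _draw_subjects(config, rng)
    start_date = pd.Timestamp(config.start_date).date()

    series, diary = [], {}
    shape_rows, night_levels = [], []
    for _, row in subjects.iterrows():
        nights = _subject_nights(config, row, start_date, rng)
        diary[row["id"]] = nights
        shape = rng.normal(0.0, config.shape_sd, size=(2, config.shape_harmonics))
        shape_rows.append(";".join(f"{v:.6f}" for v in shape.ravel()))
        night_level = float(rng.normal(0.0, config.night_level_sd))
        night_levels.append(night_level)
        mu = latent_rate(
            config, row, nights, start_date, shape_coefs=shape, night_level=night_level
        )
        p = config.dispersion / (config.dispersion + mu)
        counts = rng.negative_binomial(config.dispersion, p)
        s = EpochSeries(
            subject_id=row["id"],
            start=pd.Timestamp(start_date),
            epoch_minutes=config.epoch_minutes,
            counts=counts,
            missing=np.zeros(counts.size, dtype=bool),
        )
        if config.gap_rate > 0:
            s = apply_gaps(s, config.gap_rate, seed=int(rng.integers(2**31)))
        series.append(s)
    subjects = subjects.assign(shape_coefs=shape_rows, night_level=night_levels)
    return SimulatedCohort(series=series, truth=subjects, diary=diary, config=config)


def apply_gaps(
    series: EpochSeries, gap_rate: float, seed: int, mode: str = "day", span_hours: tuple = (2, 6)
) -> EpochSeries:
    """Mark collar-off spans missing (never zero).

    ``mode='day'`` masks whole recorded days independently with
    probability ``gap_rate``; ``mode='hours'`` masks, with the same
    per-day probability, one contiguous span of ``span_hours`` (uniform)
    starting at a uniform epoch of that day.
    """
    if not 0 <= gap_rate <= 1:
        raise SimulationError("gap_rate must be in [0, 1]")
    if mode not in {"day", "hours"}:
        raise SimulationError(f"unknown gap mode {mode!r}")
    out = series.copy()
    if gap_rate == 0:
        return out
    rng = np.random.default_rng(seed)
    eppd = MINUTES_PER_DAY // series.epoch_minutes
    n_days = int(np.ceil(series.n_epochs / eppd))
    for d in range(n_days):
        if rng.random() >= gap_rate:
            continue
        lo = d * eppd
        hi = min((d + 1) * eppd, series.n_epochs)
        if mode == "day":
            out.missing[lo:hi] = True
        else:
            span = int(rng.uniform(*span_hours) * 60 / series.epoch_minutes)
            start = lo + int(rng.integers(0, eppd))
            out.missing[start : min(start + span, hi)] = True
    return out
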