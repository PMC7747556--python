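"""Reading, validating and assembling actigraphy cohorts.

The ingestion boundary is CSV: one epoch file per subject (ISO-8601
timestamp, integer activity count, optional missing flag), a cohort
metadata table (id, age, sex, mass) and a night-window diary
(id, date, bedtime, waketime). Proprietary binary monitor files are out
of scope; export them to CSV first.

Missing wear time (collar off) is represented by an explicit missing
mask, never by zero counts: a zero is a real observation of no movement,
a masked epoch is no observation at all.
"""

from __future__ import annotations

import datetime as _dt
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._clock import (
    MINUTES_PER_DAY,
    circular_length,
    fmt_clock,
    in_window,
    parse_clock,
)

logger = logging.getLogger("actiflm")

#: Fallback night window applied when the diary has no row for a date:
#: 22:00 -> 07:00, matching typical owner-reported bed and wake times.
DEFAULT_NIGHT_WINDOW = (22 * 60, 7 * 60)

#: A stratum-day whose missing-epoch fraction exceeds this yields no summary.
MAX_MISSING_FRACTION = 0.5


class ActigraphyError(ValueError):
    """Raised for invalid or inconsistent input data."""


@dataclass
class EpochSeries:
    """One subject's activity counts on a strictly regular epoch grid.

    Parameters
    ----------
    subject_id : str
        Identifier linking the series to metadata and diary rows.
    start : pandas.Timestamp
        Timestamp of the first epoch.
    epoch_minutes : int
        Epoch length; must divide 1440 (one day).
    counts : ndarray of int
        One count per epoch. Values at masked positions are ignored.
    missing : ndarray of bool
        True where the epoch was not observed (collar off / grid gap).
    """

    subject_id: str
    start: pd.Timestamp
    epoch_minutes: int
    counts: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.missing is None:
            self.missing = np.zeros(self.counts.shape, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.counts.ndim != 1 or self.counts.shape != self.missing.shape:
            raise ActigraphyError("counts and missing must be equal-length 1-d arrays")
        if MINUTES_PER_DAY % int(self.epoch_minutes) != 0:
            raise ActigraphyError(f"epoch_minutes={self.epoch_minutes} does not divide 1440")
        observed = self.counts[~self.missing]
        if observed.size and observed.min() < 0:
            raise ActigraphyError("negative activity counts")

    # -- derived views ---------------------------------------------------

    @property
    def n_epochs(self) -> int:
        return int(self.counts.size)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.n_epochs, freq=f"{self.epoch_minutes}min")

    @property
    def minute_of_day(self) -> np.ndarray:
        start_min = self.start.hour * 60 + self.start.minute
        return (start_min + np.arange(self.n_epochs) * self.epoch_minutes) % MINUTES_PER_DAY

    @property
    def dates(self) -> np.ndarray:
        """Calendar date of each epoch."""
        return self.timestamps.date

    def calendar_days(self) -> pd.DataFrame:
        """Distinct calendar dates with weekday/weekend flag."""
        d = pd.DataFrame({"date": pd.unique(self.dates)})
        d["day_type"] = [day_type_of(x) for x in d["date"]]
        return d

    def masked_counts(self) -> np.ndarray:
        """Counts as float with NaN at masked epochs."""
        out = self.counts.astype(float)
        out[self.missing] = np.nan
        return out

    def copy(self) -> "EpochSeries":
        return replace(self, counts=self.counts.copy(), missing=self.missing.copy())


def day_type_of(date: _dt.date) -> str:
    return "weekend" if date.weekday() >= 5 else "weekday"


@dataclass(frozen=True)
class NightWindow:
    """Owner-reported night for one subject-date.

    The night starts at ``bedtime`` on ``date`` and ends at ``waketime``
    the following morning (the window wraps midnight whenever waketime
    precedes bedtime on the clock).
    """

    subject_id: str
    date: _dt.date
    bedtime: int  # minutes since midnight
    waketime: int

    def __post_init__(self) -> None:
        if not (0 < circular_length(self.bedtime, self.waketime) < MINUTES_PER_DAY):
            raise ActigraphyError(
                f"night window for {self.subject_id} on {self.date} has "
                f"non-positive circular length"
            )


@dataclass
class CohortTable:
    """Analysis-ready cohort: metadata, epoch series and diaries keyed by id."""

    subjects: pd.DataFrame  # columns: id, age, sex, mass [, snore_score]
    series: dict
    diaries: dict

    def __post_init__(self) -> None:
        ids = set(self.subjects["id"].astype(str))
        orphans = sorted(set(self.series) - ids)
        if orphans:
            raise ActigraphyError(f"series without metadata row: {orphans}")
        meta = self.subjects
        if not np.all(np.isfinite(meta["age"])) or (meta["age"] <= 0).any():
            raise ActigraphyError("ages must be finite and positive")
        if not np.all(np.isfinite(meta["mass"])) or (meta["mass"] <= 0).any():
            raise ActigraphyError("masses must be finite and positive")
        bad_sex = set(meta["sex"]) - {"F", "M"}
        if bad_sex:
            raise ActigraphyError(f"sex must be F or M, got {sorted(bad_sex)}")


# ---------------------------------------------------------------------------
# epoch CSV
# ---------------------------------------------------------------------------

def write_epoch_csv(series: EpochSeries, path) -> None:
    """Write an epoch series as CSV (timestamp, count, missing flag)."""
    df = pd.DataFrame(
        {
            "timestamp": series.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
            "count": [("" if m else str(c)) for c, m in zip(series.counts, series.missing)],
            "missing": series.missing.astype(int),
        }
    )
    df.to_csv(path, index=False)


def read_epoch_csv(path, epoch_minutes: int | None = None, subject_id: str | None = None) -> EpochSeries:
    """Read one subject's epoch CSV into a validated :class:`EpochSeries`.

    Accepted dialects: with or without a header row, with or without a
    units row under the header, with or without a ``missing`` flag
    column. Holes in the timestamp grid are filled with missing-marked
    epochs; non-monotone or duplicated timestamps are hard errors.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, header=None, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError as e:
        raise ActigraphyError(f"{path}: empty epoch file") from e
    if raw.empty:
        raise ActigraphyError(f"{path}: empty epoch file")

    def _is_ts(cell) -> bool:
        try:
            ts = pd.Timestamp(str(cell))
        except Exception:
            return False
        return ts is not pd.NaT

    rows = raw
    names = ["timestamp", "count", "missing"][: raw.shape[1]]
    if not _is_ts(raw.iloc[0, 0]):
        # header row present; possibly a units row beneath it
        names = [str(c).strip().lower() for c in raw.iloc[0]]
        rows = raw.iloc[1:]
        if len(rows) and not _is_ts(rows.iloc[0, 0]):
            rows = rows.iloc[1:]  # units row
    if len(rows) == 0:
        raise ActigraphyError(f"{path}: no data rows")
    rows = rows.reset_index(drop=True)
    rows.columns = names
    if "timestamp" not in names or "count" not in names:
        raise ActigraphyError(f"{path}: expected 'timestamp' and 'count' columns, got {names}")

    ts = pd.to_datetime(rows["timestamp"])
    diffs = ts.diff().dropna()
    if (diffs <= pd.Timedelta(0)).any():
        i = int(np.argmax(diffs.values <= np.timedelta64(0))) + 1
        if diffs.iloc[i - 1] == pd.Timedelta(0):
            raise ActigraphyError(f"{path}: duplicated timestamp at row {i}: {ts.iloc[i]}")
        raise ActigraphyError(f"{path}: non-monotone timestamps at row {i}: {ts.iloc[i]}")

    if epoch_minutes is None:
        if len(ts) < 2:
            raise ActigraphyError(f"{path}: cannot infer epoch length from one row")
        epoch_minutes = int(diffs.median() / pd.Timedelta(minutes=1))
    step = pd.Timedelta(minutes=epoch_minutes)
    off_grid = ((ts - ts.iloc[0]) % step) != pd.Timedelta(0)
    if off_grid.any():
        i = int(np.argmax(off_grid.values))
        raise ActigraphyError(f"{path}: timestamp off the {epoch_minutes}-min grid at row {i}")

    grid = pd.date_range(ts.iloc[0], ts.iloc[len(ts) - 1], freq=step)
    counts = np.zeros(len(grid), dtype=np.int64)
    missing = np.ones(len(grid), dtype=bool)
    idx = ((ts - ts.iloc[0]) // step).astype(int).to_numpy()

    count_str = rows["count"].fillna("").astype(str).str.strip()
    flagged = (
        rows["missing"].fillna("0").astype(str).str.strip().isin({"1", "true", "True"})
        if "missing" in names
        else pd.Series(False, index=rows.index)
    )
    row_missing = flagged | (count_str == "")
    vals = pd.to_numeric(count_str.where(~row_missing, other="0"))
    if (vals < 0).any():
        raise ActigraphyError(f"{path}: negative count")
    counts[idx] = vals.to_numpy().astype(np.int64)
    missing[idx] = row_missing.to_numpy()

    return EpochSeries(
        subject_id=subject_id or path.stem,
        start=grid[0],
        epoch_minutes=epoch_minutes,
        counts=counts,
        missing=missing,
    )


# ---------------------------------------------------------------------------
# metadata / diary CSV
# ---------------------------------------------------------------------------

def read_metadata_csv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, dtype={"id": str})
    required = {"id", "age", "sex", "mass"}
    if not required <= set(meta.columns):
        raise ActigraphyError(f"{path}: metadata needs columns {sorted(required)}")
    return meta


def read_diary_csv(path) -> dict:
    """Diary CSV (id, date, bedtime, waketime) -> {id: [NightWindow, ...]}."""
    df = pd.read_csv(path, dtype={"id": str})
    out: dict = {}
    for _, r in df.iterrows():
        w = NightWindow(
            subject_id=r["id"],
            date=pd.Timestamp(r["date"]).date(),
            bedtime=parse_clock(str(r["bedtime"])),
            waketime=parse_clock(str(r["waketime"])),
        )
        out.setdefault(r["id"], []).append(w)
    return out


def write_diary_csv(diaries: dict, path) -> None:
    rows = [
        {
            "id": w.subject_id,
            "date": w.date.isoformat(),
            "bedtime": fmt_clock(w.bedtime),
            "waketime": fmt_clock(w.waketime),
        }
        for ws in diaries.values()
        for w in ws
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_cohort(cohort_dir) -> CohortTable:
    """Load a cohort directory written by the simulator or by hand.

    Expects ``metadata.csv``, ``diary.csv`` and one ``epochs_<id>.csv``
    per subject.
    """
    cohort_dir = Path(cohort_dir)
    meta = read_metadata_csv(cohort_dir / "metadata.csv")
    diaries = read_diary_csv(cohort_dir / "diary.csv") if (cohort_dir / "diary.csv").exists() else {}
    series = {}
    for sid in meta["id"]:
        f = cohort_dir / f"epochs_{sid}.csv"
        if not f.exists():
            raise ActigraphyError(f"missing epoch file for subject {sid}: {f}")
        series[sid] = read_epoch_csv(f, subject_id=sid)
    return CohortTable(subjects=meta, series=series, diaries=diaries)


# ---------------------------------------------------------------------------
# day/night classification and summaries
# ---------------------------------------------------------------------------

def classify_day_night(
    series: EpochSeries,
    windows: list | None,
    default_window: tuple = DEFAULT_NIGHT_WINDOW,
) -> pd.DataFrame:
    """Label every epoch day or night and attribute it to a stratum date.

    Nighttime is the half-open window [bedtime, waketime) wrapping
    midnight; everything else is daytime. A night is attributed to the
    calendar date its bedtime falls on, so post-midnight epochs carry
    the previous date. When no diary window exists for a date the
    default window is applied and a warning is logged.

    Returns a DataFrame with columns ``label`` ('day'/'night') and
    ``stratum_date``; raises on overlapping windows for one date.
    """
    by_date: dict = {}
    for w in windows or []:
        if w.date in by_date:
            raise ActigraphyError(
                f"overlapping night windows for {series.subject_id} on {w.date}"
            )
        by_date[w.date] = w

    ts = series.timestamps
    first_date = ts[0].date()
    last_date = ts[-1].date()
    day0 = pd.Timestamp(first_date)

    abs_minute = ((ts - day0) / pd.Timedelta(minutes=1)).to_numpy().astype(np.int64)
    labels = np.full(series.n_epochs, "day", dtype=object)
    stratum = np.array([pd.Timestamp(d) for d in series.dates], dtype=object)
    night_hits = np.zeros(series.n_epochs, dtype=np.int64)

    # expected epochs per (date, label) on the full clock, independent of how
    # much of the stratum the recording actually covers; summaries use this
    # so that clipped first/last nights are not reported as biased means
    em = series.epoch_minutes
    expected: dict = {}
    day_overlap: dict = {}

    d = first_date - _dt.timedelta(days=1)
    while d <= last_date:
        w = by_date.get(d)
        bed, wake = default_window if w is None else (w.bedtime, w.waketime)
        start = int((pd.Timestamp(d) - day0) / pd.Timedelta(minutes=1)) + bed
        end = start + circular_length(bed, wake)
        mask = (abs_minute >= start) & (abs_minute < end)
        if w is None and mask.any():
            logger.warning(
                "no diary night for %s on %s; default window %s-%s applied",
                series.subject_id, d, fmt_clock(bed), fmt_clock(wake),
            )
        labels[mask] = "night"
        stratum[mask] = pd.Timestamp(d)
        night_hits[mask] += 1
        expected[(d, "night")] = circular_length(bed, wake) // em
        for date in (d, d + _dt.timedelta(days=1)):
            day_abs = int((pd.Timestamp(date) - day0) / pd.Timedelta(minutes=1))
            overlap = max(0, min(end, day_abs + MINUTES_PER_DAY) - max(start, day_abs))
            day_overlap[date] = day_overlap.get(date, 0) + overlap
        d += _dt.timedelta(days=1)

    for date in pd.unique(series.dates):
        expected[(date, "day")] = (
            MINUTES_PER_DAY - day_overlap.get(date, 0)
        ) // em

    if (night_hits > 1).any():
        raise ActigraphyError(f"overlapping night windows for {series.subject_id}")

    out = pd.DataFrame(
        {"label": labels, "stratum_date": [t.date() for t in stratum]},
        index=ts,
    )
    out.attrs["expected_epochs"] = expected
    return out


def summarize_activity(series: EpochSeries, labels: pd.DataFrame) -> pd.DataFrame:
    """Per-date mean counts by stratum.

    Means are over non-missing epochs only. A stratum-day yields NaN when
    more than half of its *expected* epochs are unobserved — whether
    masked (collar off) or simply outside the recording (a clipped first
    or last night) — so partial strata never enter as biased means.
    ``day_type`` is weekday/weekend from the stratum date.
    """
    df = labels.copy()
    df["count"] = series.masked_counts()
    df["missing"] = series.missing
    expected = labels.attrs.get("expected_epochs", {})

    rows = []
    for date in sorted(set(df["stratum_date"])):
        rec = {"subject_id": series.subject_id, "date": date, "day_type": day_type_of(date)}
        sub = df[df["stratum_date"] == date]
        for label, col in (("day", "daytime_mean_count"), ("night", "nighttime_mean_count")):
            s = sub[sub["label"] == label]
            n_expected = max(expected.get((date, label), len(s)), len(s))
            n_observed = int((~s["missing"]).sum())
            if len(s) == 0 or n_observed < (1 - MAX_MISSING_FRACTION) * n_expected:
                rec[col] = np.nan
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    rec[col] = float(np.nanmean(s["count"].to_numpy()))
        rows.append(rec)
    return pd.DataFrame(rows)


def cohort_summaries(cohort: CohortTable, default_window: tuple = DEFAULT_NIGHT_WINDOW) -> pd.DataFrame:
    """Concatenated day/night summaries for every subject in a cohort."""
    parts = []
    for sid, series in cohort.series.items():
        labels = classify_day_night(series, cohort.diaries.get(sid), default_window)
        parts.append(summarize_activity(series, labels))
    return pd.concat(parts, ignore_index=True)


def qc_report(cohort: CohortTable) -> pd.DataFrame:
    """Per-subject wear-time quality control table.

    Collar-off spans are kept as missing epochs (never zeros) and simply
    excluded from downstream means; this table makes their extent visible.
    """
    rows = []
    for sid, s in cohort.series.items():
        rows.append(
            {
                "id": sid,
                "n_epochs": s.n_epochs,
                "n_days": len(set(s.dates)),
                "missing_fraction": float(s.missing.mean()),
                "median_count": float(np.nanmedian(s.masked_counts())),
                "start": s.start.isoformat(),
            }
        )
    return pd.DataFrame(rows)
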