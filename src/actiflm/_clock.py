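"""Clock arithmetic on minutes-since-midnight integers.

All intervals are half-open [start, end) and interpreted on the circular
24-h clock; a window whose end precedes its start wraps midnight.
"""

from __future__ import annotations

MINUTES_PER_DAY = 1440


def hours_to_minutes(h: float) -> int:
    """Clock hours (e.g. 22.5) -> whole minutes since midnight."""
    m = int(round(h * 60.0))
    return m % MINUTES_PER_DAY


def circular_length(start_min: int, end_min: int) -> int:
    """Length of [start, end) on the circular clock, in minutes (0..1439)."""
    return (end_min - start_min) % MINUTES_PER_DAY


def in_window(minute_of_day, start_min: int, end_min: int):
    """Membership of clock minutes in a possibly midnight-wrapping window.

    Works elementwise on arrays. A zero-length window contains nothing.
    """
    m = minute_of_day % MINUTES_PER_DAY
    if start_min == end_min:
        return m != m  # all False, preserving array shape
    if start_min < end_min:
        return (m >= start_min) & (m < end_min)
    return (m >= start_min) | (m < end_min)


def fmt_clock(minute_of_day: int) -> str:
    m = int(minute_of_day) % MINUTES_PER_DAY
    return f"{m // 60:02d}:{m % 60:02d}"


def parse_clock(text: str) -> int:
    """'HH:MM' -> minutes since midnight."""
    hh, mm = text.strip().split(":")
    m = int(hh) * 60 + int(mm)
    if not 0 <= m < MINUTES_PER_DAY:
        raise ValueError(f"clock time out of range: {text!r}")
    return m
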