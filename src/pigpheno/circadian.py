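"""Actigraphy binning, daily activity profiles and sleep-wake segmentation.

Step counts from a wearable tracker are summed into fixed-width bins (15 min
in the study) per calendar day and averaged across full days to give a daily
activity profile; the most-active contiguous window of a given width is then
located by exhaustive scan.  Sleep is segmented per night (noon-to-noon, so a
night belongs to the day it starts) as the span from the first long run of
quiet bins starting in the evening search window to the end of the last such
run inside the morning search window; nights without a qualifying run are
flagged undetermined, never fabricated.

Defaults follow the study's housing (12-h light cycle 07:00-19:00): evening
search 19:00-03:00, morning search 05:00-11:00, quiet = 0 steps/bin sustained
for >= 4 bins (1 h).  All are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ActivitySeries, ValidationError

logger = logging.getLogger(__name__)

MIN_PER_DAY = 24 * 60


@dataclass
class DailyProfile:
    """Mean per-bin step counts across full days."""

    bin_width: int  # minutes
    bins: np.ndarray  # mean steps per bin, length = span / bin_width
    per_day: np.ndarray  # (n_days, n_bins) per-day sums
    days: list = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def bin_start_minutes(self) -> np.ndarray:
        """Start of each bin in minutes since midnight."""
        return np.arange(self.n_bins) * self.bin_width


@dataclass
class NightRecord:
    """Sleep bout of one night (the night of ``date``, noon-to-noon)."""

    date: pd.Timestamp
    onset: pd.Timestamp | None
    wake: pd.Timestamp | None
    duration_h: float
    determined: bool


@dataclass
class SleepRecord:
    nights: list[NightRecord] = field(default_factory=list)

    @property
    def determined(self) -> list[NightRecord]:
        return [n for n in self.nights if n.determined]

    def durations(self) -> np.ndarray:
        return np.array([n.duration_h for n in self.determined])


def _full_days(series: ActivitySeries, bin_width: int) -> list[pd.Timestamp]:
    """Days whose sampling covers midnight-to-midnight to within one bin."""
    ts = series.data["timestamp"]
    days = []
    for day, grp in ts.groupby(ts.dt.normalize()):
        first = (grp.min() - day).total_seconds() / 60.0
        last = (day + pd.Timedelta(days=1) - grp.max()).total_seconds() / 60.0
        if first < bin_width and last <= bin_width:
            days.append(day)
        else:
            logger.info("excluding partial day %s", day.date())
    return sorted(days)


def bin_activity(series: ActivitySeries, bin_width: int = 15, span: int = MIN_PER_DAY) -> DailyProfile:
    """Per-bin sums per full day, then the mean across days.

    ``bin_width`` (minutes) must divide ``span``; partial days are excluded
    with a log message; an error is raised if no full day remains.
    """
    if span % bin_width != 0:
        raise ValueError("bin_width must divide the span")
    n_bins = span // bin_width
    days = _full_days(series, bin_width)
    if not days:
        raise ValidationError("no full day covered by the series")
    df = series.data
    per_day = np.zeros((len(days), n_bins))
    for i, day in enumerate(days):
        sel = df[df["timestamp"].dt.normalize() == day]
        minute = ((sel["timestamp"] - day).dt.total_seconds() / 60.0).to_numpy()
        which = np.floor_divide(minute, bin_width).astype(int)
        keep = which < n_bins
        np.add.at(per_day[i], which[keep], sel["steps"].to_numpy(float)[keep])
    return DailyProfile(bin_width=bin_width, bins=per_day.mean(axis=0), per_day=per_day, days=days)


def peak_window(profile: DailyProfile, window: int = 240) -> tuple[int, float]:
    """Start (minutes since midnight) and mean level of the most-active window.

    The window is ``window`` minutes of contiguous bins; ties break to the
    earliest start.
    """
    if window % profile.bin_width != 0:
        raise ValueError("window must be a multiple of bin_width")
    w = window // profile.bin_width
    if w > profile.n_bins or w < 1:
        raise ValueError("window must fit within the profile span")
    csum = np.concatenate(([0.0], np.cumsum(profile.bins)))
    means = (csum[w:] - csum[:-w]) / w
    start_bin = int(np.argmax(means))  # argmax returns the earliest maximum
    return start_bin * profile.bin_width, float(means[start_bin])


def _quiet_runs(quiet: np.ndarray) -> list[tuple[int, int]]:
    """(start, end) bin index pairs of maximal quiet runs; end is exclusive."""
    runs = []
    start = None
    for i, q in enumerate(quiet):
        if q and start is None:
            start = i
        elif not q and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(quiet)))
    return runs


def sleep_segments(
    series: ActivitySeries,
    threshold: float = 0.0,
    min_run: int = 4,
    bin_width: int = 15,
    evening_window: tuple[float, float] = (19.0, 3.0),
    morning_window: tuple[float, float] = (5.0, 11.0),
) -> SleepRecord:
    """Segment each night's sleep bout from binned activity.

    Nights run noon-to-noon.  Sleep onset is the start of the first run of
    >= ``min_run`` consecutive bins with <= ``threshold`` steps that begins
    inside the evening search window; wake is the end of the last such run
    that ends inside the morning search window.  Activity bursts shorter
    than ``min_run`` inside the night do not break the segmentation (onset
    and wake come from the flanking long quiet runs).  A night without both
    marks is flagged undetermined.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    df = series.data
    ts = df["timestamp"]
    n_bins = MIN_PER_DAY // bin_width
    # hours since noon for the window tests (evening may cross midnight)
    ev_lo = evening_window[0] - 12.0
    ev_hi = evening_window[1] - 12.0 + (24.0 if evening_window[1] < evening_window[0] else 0.0)
    ev_hi += 24.0 if ev_hi < ev_lo else 0.0
    mo_lo = morning_window[0] + 12.0
    mo_hi = morning_window[1] + 12.0
    record = SleepRecord()
    for day in sorted(ts.dt.normalize().unique()):
        noon = day + pd.Timedelta(hours=12)
        night_end = noon + pd.Timedelta(days=1)
        first = ts.min()
        last = ts.max()
        if first > noon + pd.Timedelta(minutes=bin_width) or last < night_end - pd.Timedelta(
            minutes=bin_width
        ):
            continue  # night not fully covered by the recording
        sel = df[(ts >= noon) & (ts < night_end)]
        minute = ((sel["timestamp"] - noon).dt.total_seconds() / 60.0).to_numpy()
        bins = np.zeros(n_bins)
        which = np.floor_divide(minute, bin_width).astype(int)
        np.add.at(bins, which, sel["steps"].to_numpy(float))
        quiet = bins <= threshold
        runs = [(s, e) for s, e in _quiet_runs(quiet) if e - s >= min_run]
        hours_per_bin = bin_width / 60.0
        onset_bin = next(
            (s for s, e in runs if ev_lo <= s * hours_per_bin < ev_hi), None
        )
        wake_bin = None
        for s, e in runs:
            if mo_lo < e * hours_per_bin <= mo_hi and (onset_bin is None or e * hours_per_bin > onset_bin * hours_per_bin):
                wake_bin = e
        if onset_bin is None or wake_bin is None or wake_bin <= onset_bin:
            record.nights.append(
                NightRecord(date=day, onset=None, wake=None, duration_h=float("nan"), determined=False)
            )
            logger.info("night of %s undetermined", day.date())
            continue
        onset = noon + pd.Timedelta(minutes=onset_bin * bin_width)
        wake = noon + pd.Timedelta(minutes=wake_bin * bin_width)
        duration = (wake - onset).total_seconds() / 3600.0
        if not 0 < duration < 24:
            raise ValidationError("night duration outside (0, 24) h")
        record.nights.append(
            NightRecord(date=day, onset=onset, wake=wake, duration_h=duration, determined=True)
        )
    return record


def sleep_summary(record: SleepRecord) -> tuple[float, float, int]:
    """(mean hours, SEM hours, n determined nights); SEM is NaN for n < 2."""
    d = record.durations()
    n = len(d)
    if n == 0:
        return float("nan"), float("nan"), 0
    mean = float(d.mean())
    sem = float(d.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    if n == 1:
        logger.info("single determined night: SEM undefined")
    return mean, sem, n
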