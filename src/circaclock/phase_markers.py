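"""Daily activity profiles and circadian phase markers under LD entrainment.

Three phase markers summarise a day of activity in Zeitgeber time (ZT 0 =
lights-on): the *onset* (first sustained rise of activity above the night
baseline), the *peak* (maximum of the 30-min moving-average-smoothed minute
track) and the *offset* (first sustained return to the night level after the
peak).  Onset and offset are read from 20-min bin sums; the peak from
smoothed minute data.  All markers are circular quantities on the 24-h cycle
and are averaged with circular (vector) means so phases spanning midnight are
handled correctly.

Operationalisation of the night baseline: with b and s the mean and SD of the
20-min bins inside a reference night window (default: 4 h centered on the
middle of the scheduled dark phase — the span farthest from both light
transitions and quiescent under every activity template considered here,
including short-day profiles whose onset precedes lights-on), the
onset is the start of the first bin — scanning circularly from the middle of
the dark phase — whose value exceeds b + 2s with the following bin not lower,
and the offset is the start of the first bin after the day's maximum whose
value has dropped to ≤ b + 2s for two consecutive bins.  Threshold
multiplier, run length and window are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dam_io import (
    MINUTES_PER_DAY,
    ActivityRecord,
    BinnedSeries,
    mark_dead,
)

logger = logging.getLogger("circaclock")

__all__ = [
    "MarkerSettings",
    "DailyProfile",
    "PhaseMarkers",
    "circular_mean_h",
    "circular_sd_h",
    "daily_profile",
    "detect_onset",
    "detect_offset",
    "detect_peak",
    "markers_for_record",
    "cohort_markers",
    "summarize_markers",
]


# ---------------------------------------------------------------------------
# Circular statistics on the 24-h cycle
# ---------------------------------------------------------------------------


def circular_mean_h(hours, period: float = 24.0) -> float:
    """Circular (vector) mean of phases in hours, in [0, period)."""
    h = np.asarray([v for v in np.atleast_1d(hours) if not np.isnan(v)], dtype=float)
    if h.size == 0:
        return float("nan")
    ang = 2 * np.pi * h / period
    mean_ang = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    out = (mean_ang * period / (2 * np.pi)) % period
    return float(out if out < period else 0.0)


def circular_sd_h(hours, period: float = 24.0) -> float:
    """Circular standard deviation (hours), sqrt(-2 ln R) scaled to the cycle."""
    h = np.asarray([v for v in np.atleast_1d(hours) if not np.isnan(v)], dtype=float)
    if h.size == 0:
        return float("nan")
    ang = 2 * np.pi * h / period
    r = np.hypot(np.sin(ang).mean(), np.cos(ang).mean())
    r = min(max(r, 1e-12), 1.0)
    return float(np.sqrt(-2 * np.log(r)) * period / (2 * np.pi))


@dataclass(frozen=True)
class MarkerSettings:
    """Tunables of the marker procedure (defaults are the declared dialect)."""

    bin_minutes: int = 20         # onset/offset track bin width
    smooth_minutes: int = 30      # moving-average width for the peak track
    threshold_sd: float = 2.0     # night baseline threshold = b + threshold_sd * s
    run_bins: int = 2             # consecutive bins required at/below level
    night_window_h: float = 4.0   # reference window width, centered on mid-dark
    skip_days: int = 4            # entrainment days excluded from analysis


# ---------------------------------------------------------------------------
# Daily profiles
# ---------------------------------------------------------------------------


@dataclass
class DailyProfile:
    """Average activity per ZT bin across days and individuals.

    ``mean_activity`` is in beam crosses per minute (bin sums divided by the
    bin width), covering exactly [0, 24) ZT.
    """

    zt_bins: np.ndarray       # bin centers (h)
    mean_activity: np.ndarray
    bin_minutes: int
    n_days: int               # total day-chunks averaged
    n_individuals: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"zt_h": self.zt_bins, "activity_per_min": self.mean_activity})


def _alive_whole_days(record: ActivityRecord) -> int:
    return record.alive_until // MINUTES_PER_DAY


def daily_profile(records: list[ActivityRecord], skip_days: int = 4,
                  bin_minutes: int = 20, quiet_hours: float = 24.0) -> DailyProfile:
    """Fold LD recordings on ZT and average across days, then individuals.

    The first ``skip_days`` entrainment days are excluded.  Only complete
    days before an animal's death enter the average, so dead spans never
    dilute the denominator.  All records must share one schedule.
    """
    if not records:
        raise ValueError("no records")
    sched = records[0].schedule
    for rec in records[1:]:
        if rec.schedule.segments != sched.segments:
            raise ValueError("records mix different light schedules")
    if sched.total_days <= skip_days:
        raise ValueError(
            f"nothing left after skipping {skip_days} of {sched.total_days} days"
        )
    bins_per_day = MINUTES_PER_DAY // bin_minutes
    acc = np.zeros(bins_per_day)
    total_days = 0
    n_ind = 0
    for rec in records:
        rec = mark_dead(rec, quiet_hours)
        days = _alive_whole_days(rec)
        day_tracks = []
        for d in range(skip_days, days):
            seg = rec.counts[d * MINUTES_PER_DAY:(d + 1) * MINUTES_PER_DAY]
            day_tracks.append(seg.reshape(bins_per_day, bin_minutes).sum(axis=1))
        if not day_tracks:
            continue
        acc += np.mean(day_tracks, axis=0)
        total_days += len(day_tracks)
        n_ind += 1
    if n_ind == 0:
        raise ValueError("no usable days in any record")
    centers = (np.arange(bins_per_day) + 0.5) * bin_minutes / 60.0
    return DailyProfile(
        zt_bins=centers,
        mean_activity=acc / n_ind / bin_minutes,
        bin_minutes=bin_minutes,
        n_days=total_days,
        n_individuals=n_ind,
    )


# ---------------------------------------------------------------------------
# Marker detection on a single day
# ---------------------------------------------------------------------------


def _origin_h(light_hours: float, origin_h: float | None) -> float:
    """Scan origin: middle of the scheduled dark phase unless overridden."""
    return (light_hours + 24.0) / 2.0 if origin_h is None else origin_h


def _night_stats(values: np.ndarray, bin_minutes: int, origin_h: float,
                 night_window_h: float) -> tuple[float, float]:
    """Mean and SD of the bins in the night reference window.

    The window spans ``night_window_h`` hours centered on the scan origin
    (mid-dark by default), so it stays clear of activity that anticipates
    lights-on or persists after lights-off.
    """
    nb = len(values)
    first = int(round((origin_h - night_window_h / 2.0) * 60 / bin_minutes))
    n_ref = int(round(night_window_h * 60 / bin_minutes))
    ref = values[[(first + j) % nb for j in range(n_ref)]]
    return float(ref.mean()), float(ref.std(ddof=1))


def detect_onset(day_track: BinnedSeries, light_hours: float,
                 settings: MarkerSettings = MarkerSettings(),
                 origin_h: float | None = None) -> float:
    """Activity onset (ZT h) of one day's 20-min track, or NaN if undefined.

    Scans circularly from the middle of the dark phase for the first bin
    above the night threshold b + 2s whose following bin is not lower, and
    returns that bin's start.  ``origin_h`` overrides the scan origin (and
    with it the center of the night reference window).
    """
    v = np.asarray(day_track.values, dtype=float)
    nb = len(v)
    if v.max() == v.min():
        return float("nan")
    o = _origin_h(light_hours, origin_h)
    b, s = _night_stats(v, day_track.bin_minutes, o, settings.night_window_h)
    thr = b + settings.threshold_sd * s
    start = int(round(o * 60 / day_track.bin_minutes)) % nb
    for k in range(nb):
        i = (start + k) % nb
        if v[i] > thr and v[(i + 1) % nb] >= v[i]:
            return float(i * day_track.bin_minutes / 60.0)
    return float("nan")


def detect_offset(day_track: BinnedSeries, light_hours: float,
                  settings: MarkerSettings = MarkerSettings(),
                  origin_h: float | None = None) -> float:
    """Activity offset (ZT h): first sustained return to the night level.

    Finds the day's maximum bin (circular scan order from mid-dark breaks
    ties) and returns the start of the first bin after it whose value is
    ≤ b + 2s for ``run_bins`` consecutive bins.  NaN when the day never rises
    above the night level (nothing to offset from) or never returns to it.
    """
    v = np.asarray(day_track.values, dtype=float)
    nb = len(v)
    if v.max() == v.min():
        return float("nan")
    o = _origin_h(light_hours, origin_h)
    b, s = _night_stats(v, day_track.bin_minutes, o, settings.night_window_h)
    thr = b + settings.threshold_sd * s
    if v.max() <= thr:
        return float("nan")
    start = int(round(o * 60 / day_track.bin_minutes)) % nb
    order = [(start + k) % nb for k in range(nb)]
    rank = {i: k for k, i in enumerate(order)}
    peak_i = max(order, key=lambda i: (v[i], -rank[i]))
    # scan forward from the bin after the peak
    pos = rank[peak_i]
    for k in range(1, nb):
        i = order[(pos + k) % nb]
        run = [order[(pos + k + r) % nb] for r in range(settings.run_bins)]
        if all(v[j] <= thr for j in run):
            return float(i * day_track.bin_minutes / 60.0)
    return float("nan")


def detect_peak(minute_values: np.ndarray, light_hours: float,
                settings: MarkerSettings = MarkerSettings(),
                origin_h: float | None = None) -> float:
    """Peak phase (ZT h) of one day's minute track after 30-min smoothing.

    A centered circular moving average suppresses isolated spikes.  The peak
    is the ZT of the smoothed maximum; an exactly tied maximum (a plateau,
    e.g. the boxcar response to a single spike) is resolved to the midpoint
    of the first maximal plateau met in a circular scan from mid-dark.
    NaN for a flat (e.g. all-zero) day.
    """
    x = np.asarray(minute_values, dtype=float)
    if len(x) != MINUTES_PER_DAY:
        raise ValueError("detect_peak needs one full day of minute data")
    w = settings.smooth_minutes
    kernel = np.ones(w) / w
    sm = np.convolve(np.concatenate([x[-(w // 2):], x, x[: w - w // 2 - 1]]),
                     kernel, mode="valid")
    if sm.max() == sm.min():
        return float("nan")
    start = int(round(_origin_h(light_hours, origin_h) * 60)) % MINUTES_PER_DAY
    at_max = np.roll(sm, -start) >= sm.max() - 1e-12
    first = int(np.argmax(at_max))
    length = int(np.argmin(at_max[first:])) if not at_max[first:].all() \
        else MINUTES_PER_DAY - first
    mid = start + first + (length - 1) // 2
    return float((mid % MINUTES_PER_DAY) / 60.0)


# ---------------------------------------------------------------------------
# Per-record and cohort marker extraction
# ---------------------------------------------------------------------------


def markers_for_record(record: ActivityRecord,
                       settings: MarkerSettings = MarkerSettings(),
                       quiet_hours: float = 24.0) -> pd.DataFrame:
    """Daily onset/peak/offset for one individual (entrainment days skipped).

    Returns a frame with one row per analysed day; undefined markers are NaN.
    """
    light_hours = record.schedule.ld_light_hours()
    rec = mark_dead(record, quiet_hours)
    days = _alive_whole_days(rec)
    rows = []
    for d in range(settings.skip_days, days):
        seg = rec.counts[d * MINUTES_PER_DAY:(d + 1) * MINUTES_PER_DAY]
        track20 = BinnedSeries(
            bin_minutes=settings.bin_minutes,
            values=seg.reshape(-1, settings.bin_minutes).sum(axis=1),
        )
        rows.append({
            "individual_id": rec.individual_id,
            "day": d,
            "onset_zt": detect_onset(track20, light_hours, settings),
            "peak_zt": detect_peak(seg, light_hours, settings),
            "offset_zt": detect_offset(track20, light_hours, settings),
        })
    return pd.DataFrame(rows, columns=["individual_id", "day", "onset_zt",
                                       "peak_zt", "offset_zt"])


def cohort_markers(records: list[ActivityRecord],
                   settings: MarkerSettings = MarkerSettings(),
                   quiet_hours: float = 24.0) -> pd.DataFrame:
    """Per-day markers for every individual in a cohort (one tidy frame)."""
    frames = [markers_for_record(r, settings, quiet_hours) for r in records]
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=["individual_id", "day", "onset_zt",
                                     "peak_zt", "offset_zt"])
    return pd.concat(frames, ignore_index=True)


@dataclass
class PhaseMarkers:
    """Cohort-level circular summary of the three phase markers."""

    onset_zt: float
    peak_zt: float
    offset_zt: float
    dispersion: dict          # marker -> circular SD (h) across individuals
    per_individual: pd.DataFrame  # circular means per individual
    per_day: pd.DataFrame     # the raw daily markers


def summarize_markers(per_day: pd.DataFrame) -> PhaseMarkers:
    """Average daily markers: circular mean per individual, then per group.

    Missing daily markers are excluded.  Raises if every marker is missing
    everywhere.
    """
    cols = ["onset_zt", "peak_zt", "offset_zt"]
    if len(per_day) == 0 or per_day[cols].isna().all().all():
        raise ValueError("no non-missing markers to summarize")
    per_ind = (
        per_day.groupby("individual_id")[cols]
        .agg(circular_mean_h)
        .reset_index()
    )
    group_mean = {c: circular_mean_h(per_ind[c].to_numpy()) for c in cols}
    group_sd = {c: circular_sd_h(per_ind[c].dropna().to_numpy()) for c in cols}
    return PhaseMarkers(
        onset_zt=group_mean["onset_zt"],
        peak_zt=group_mean["peak_zt"],
        offset_zt=group_mean["offset_zt"],
        dispersion=group_sd,
        per_individual=per_ind,
        per_day=per_day,
    )
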