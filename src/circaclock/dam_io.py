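"""TriKinetics DAM2 monitor I/O, light schedules, and per-individual records.

A DAM2 monitor text file is tab-delimited with one row per minute and no
header.  Each row carries 10 metadata columns — reading index, date
(``dd mmm yy``), time (``HH:MM:SS``), a status code, five device fields and a
light-sensor flag — followed by 32 beam-cross count columns, one per channel
(one animal per channel).  This module reads and writes that dialect,
attaches experiment metadata to channels, applies the automated dead-animal
filter, and bins minute counts for downstream analysis.

Time conventions: every :class:`ActivityRecord` starts at minute 0 of its
:class:`LightSchedule`, and minute 0 is lights-on of the first recorded day
(Zeitgeber time 0).  Under constant darkness (DD) the Zeitgeber scale
continues as a 24-h extrapolation of the preceding light:dark cycle, so
ZT(t) = (t / 60) mod 24 throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

logger = logging.getLogger("circaclock")

N_CHANNELS = 32
MINUTES_PER_DAY = 1440
STATUS_OK = 1

__all__ = [
    "N_CHANNELS",
    "MINUTES_PER_DAY",
    "STATUS_OK",
    "LightSegment",
    "LightSchedule",
    "MonitorFile",
    "ActivityRecord",
    "BinnedSeries",
    "DamParseError",
    "DamGapError",
    "read_dam2",
    "write_dam2",
    "attach_metadata",
    "mark_dead",
    "bin_counts",
]


class DamParseError(ValueError):
    """Raised when a DAM2 file row cannot be parsed."""


class DamGapError(ValueError):
    """Raised when timestamps are not a gap-free 1-minute grid."""


# ---------------------------------------------------------------------------
# Light schedules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LightSegment:
    """One protocol segment: an LD p:q cycle or constant darkness.

    For LD segments ``light_hours + dark_hours`` must equal 24 and each day
    starts at lights-on.  DD segments are encoded with ``light_hours = 0``.
    """

    regime: str  # "LD" or "DD"
    light_hours: float
    dark_hours: float
    n_days: int

    def __post_init__(self) -> None:
        if self.regime not in ("LD", "DD"):
            raise ValueError(f"regime must be 'LD' or 'DD', got {self.regime!r}")
        if self.regime == "LD":
            if abs(self.light_hours + self.dark_hours - 24.0) > 1e-9:
                raise ValueError("LD segment must have light_hours + dark_hours == 24")
            if self.light_hours <= 0:
                raise ValueError("LD segment needs light_hours > 0")
        else:
            if self.light_hours != 0:
                raise ValueError("DD segment must have light_hours == 0")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")

    @property
    def minutes(self) -> int:
        return self.n_days * MINUTES_PER_DAY


@dataclass(frozen=True)
class LightSchedule:
    """Declarative light protocol mapping record minutes to light state and ZT.

    ZT 0 is the lights-on instant; minute 0 of the schedule is ZT 0 of the
    first day.  All segment days span 24 h, so ZT(t) = (t/60) mod 24 holds in
    every segment, including DD, where it is the conventional extrapolation of
    the last entrained cycle.
    """

    segments: tuple[LightSegment, ...]
    zt0_clock_time: str = "08:00:00"

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule needs at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))

    @property
    def total_minutes(self) -> int:
        return sum(s.minutes for s in self.segments)

    @property
    def total_days(self) -> int:
        return self.total_minutes // MINUTES_PER_DAY

    def segment_starts(self) -> list[int]:
        """Start minute of each segment."""
        starts, t = [], 0
        for seg in self.segments:
            starts.append(t)
            t += seg.minutes
        return starts

    def segment_at(self, minute: float) -> tuple[LightSegment, int]:
        """Segment covering ``minute`` and its start minute."""
        if minute < 0 or minute >= self.total_minutes:
            raise ValueError(f"minute {minute} outside schedule [0, {self.total_minutes})")
        t = 0
        for seg in self.segments:
            if minute < t + seg.minutes:
                return seg, t
            t += seg.minutes
        raise AssertionError("unreachable")

    def zt_hours(self, minutes: np.ndarray | float) -> np.ndarray | float:
        """Zeitgeber time (h in [0, 24)) of schedule minute(s)."""
        return (np.asarray(minutes, dtype=float) / 60.0) % 24.0

    def is_light(self, minutes: np.ndarray | float) -> np.ndarray:
        """Boolean light state per minute (False everywhere in DD)."""
        m = np.atleast_1d(np.asarray(minutes, dtype=float))
        out = np.zeros(m.shape, dtype=bool)
        t = 0
        for seg in self.segments:
            in_seg = (m >= t) & (m < t + seg.minutes)
            if seg.regime == "LD":
                zt = (m / 60.0) % 24.0
                out |= in_seg & (zt < seg.light_hours)
            t += seg.minutes
        return out

    def dd_start_minute(self) -> int | None:
        """Start minute of the first DD segment, or None if the protocol has no DD."""
        t = 0
        for seg in self.segments:
            if seg.regime == "DD":
                return t
            t += seg.minutes
        return None

    def ld_light_hours(self) -> float:
        """Light hours of the last LD segment (defines the ZT day/night split)."""
        for seg in reversed(self.segments):
            if seg.regime == "LD":
                return seg.light_hours
        raise ValueError("schedule has no LD segment")

    @staticmethod
    def ld_dd(ld_light: float, ld_days: int, dd_days: int,
              zt0_clock_time: str = "08:00:00") -> "LightSchedule":
        """Entrainment-then-free-run protocol: ``ld_days`` of LD then ``dd_days`` DD."""
        return LightSchedule(
            (
                LightSegment("LD", ld_light, 24.0 - ld_light, ld_days),
                LightSegment("DD", 0.0, 24.0, dd_days),
            ),
            zt0_clock_time,
        )

    @staticmethod
    def ld_only(ld_light: float, days: int,
                zt0_clock_time: str = "08:00:00") -> "LightSchedule":
        """Pure LD protocol of ``days`` days."""
        return LightSchedule(
            (LightSegment("LD", ld_light, 24.0 - ld_light, days),), zt0_clock_time
        )


# ---------------------------------------------------------------------------
# Monitor files
# ---------------------------------------------------------------------------


@dataclass
class MonitorFile:
    """In-memory image of one DAM2 monitor file.

    ``counts`` is an (n_rows, 32) non-negative integer array; timestamps are a
    strictly increasing 1-minute grid.  ``status`` keeps the per-row device
    status code (1 = OK); rows with other codes are flagged by
    ``bad_status_rows`` but never dropped.  ``imputed`` marks rows inserted by
    the gap-filling dialect option.
    """

    monitor_id: str
    timestamps: pd.DatetimeIndex
    status: np.ndarray
    light_sensor: np.ndarray
    counts: np.ndarray
    imputed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.timestamps)
        if self.counts.shape != (n, N_CHANNELS):
            raise ValueError(
                f"counts must be (n_rows, {N_CHANNELS}); got {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.status = np.asarray(self.status, dtype=np.int64)
        self.light_sensor = np.asarray(self.light_sensor, dtype=np.int64)
        if self.imputed is None:
            self.imputed = np.zeros(n, dtype=bool)
        if n > 1:
            deltas = np.diff(self.timestamps.asi8) / 60_000_000_000
            if not np.all(deltas == 1):
                bad = np.flatnonzero(deltas != 1)
                raise DamGapError(
                    f"monitor {self.monitor_id}: non 1-min spacing at rows {bad[:10].tolist()}"
                )

    @property
    def n_rows(self) -> int:
        return len(self.timestamps)

    @property
    def bad_status_rows(self) -> np.ndarray:
        return np.flatnonzero(self.status != STATUS_OK)


_DATE_FMT = "%d %b %y"
# DAM2 rows: index, date, time, status, 5 device fields, light sensor, 32 counts
_N_META = 10
_N_COLS = _N_META + N_CHANNELS


def read_dam2(path, *, monitor_id: str | None = None,
              fill_gaps: bool = False) -> MonitorFile:
    """Read a TriKinetics DAM2 monitor file.

    Parameters
    ----------
    path : str or Path
        Tab-delimited monitor file (no header, 42 columns).
    monitor_id : str, optional
        Identifier for the monitor; defaults to the file stem.
    fill_gaps : bool
        If True, missing minutes are filled with zero-count rows flagged as
        imputed instead of raising :class:`DamGapError`.  Duplicate
        timestamps always raise.
    """
    path = str(path)
    if monitor_id is None:
        import os

        monitor_id = os.path.splitext(os.path.basename(path))[0]

    times: list[datetime] = []
    status: list[int] = []
    light: list[int] = []
    counts: list[list[int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != _N_COLS:
                raise DamParseError(
                    f"{path}:{lineno}: expected {_N_COLS} tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                ts = datetime.strptime(f"{fields[1]} {fields[2]}", _DATE_FMT + " %H:%M:%S")
                st = int(fields[3])
                ls = int(fields[9])
                row = [int(x) for x in fields[_N_META:]]
            except ValueError as exc:
                raise DamParseError(f"{path}:{lineno}: {exc}") from exc
            if any(c < 0 for c in row):
                raise DamParseError(f"{path}:{lineno}: negative count")
            times.append(ts)
            status.append(st)
            light.append(ls)
            counts.append(row)

    imputed = np.zeros(len(times), dtype=bool)
    if len(times) > 1:
        deltas = [
            int((b - a).total_seconds() // 60) for a, b in zip(times[:-1], times[1:])
        ]
        if any(d <= 0 for d in deltas):
            bad = [i + 2 for i, d in enumerate(deltas) if d <= 0]
            raise DamGapError(
                f"{path}: duplicate or backwards timestamps at lines {bad[:10]}"
            )
        if any(d > 1 for d in deltas):
            bad = [i + 2 for i, d in enumerate(deltas) if d > 1]
            if not fill_gaps:
                raise DamGapError(
                    f"{path}: time gaps before lines {bad[:10]}; "
                    "pass fill_gaps=True to zero-fill"
                )
            f_times, f_status, f_light, f_counts, f_imp = [], [], [], [], []
            for i, t in enumerate(times):
                if i > 0:
                    gap = deltas[i - 1]
                    for k in range(1, gap):
                        f_times.append(times[i - 1] + timedelta(minutes=k))
                        f_status.append(STATUS_OK)
                        f_light.append(0)
                        f_counts.append([0] * N_CHANNELS)
                        f_imp.append(True)
                f_times.append(t)
                f_status.append(status[i])
                f_light.append(light[i])
                f_counts.append(counts[i])
                f_imp.append(False)
            times, status, light, counts = f_times, f_status, f_light, f_counts
            imputed = np.array(f_imp, dtype=bool)
            logger.info("%s: zero-filled %d missing rows (flagged imputed)",
                        path, int(imputed.sum()))

    mf = MonitorFile(
        monitor_id=monitor_id,
        timestamps=pd.DatetimeIndex(times),
        status=np.array(status, dtype=np.int64),
        light_sensor=np.array(light, dtype=np.int64),
        counts=np.array(counts, dtype=np.int64).reshape(len(times), N_CHANNELS),
        imputed=imputed,
    )
    nbad = len(mf.bad_status_rows)
    if nbad:
        logger.warning("%s: %d rows with non-OK status flagged", path, nbad)
    return mf


def write_dam2(monitor: MonitorFile, path) -> None:
    """Write a MonitorFile in the DAM2 dialect; re-readable bit-exact."""
    with open(path, "w") as fh:
        for i in range(monitor.n_rows):
            ts = monitor.timestamps[i]
            meta = [
                str(i + 1),
                ts.strftime(_DATE_FMT),
                ts.strftime("%H:%M:%S"),
                str(int(monitor.status[i])),
                "1", "0", "0", "0", "0",  # device fields (unused by analysis)
                str(int(monitor.light_sensor[i])),
            ]
            row = meta + [str(int(c)) for c in monitor.counts[i]]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Per-individual records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IndividualMeta:
    """Experimental metadata for one animal."""

    population: str = ""
    latitude: float = float("nan")
    line: str = ""
    sex: str = "F"  # F or M
    mating: str = "virgin"  # virgin or mated


@dataclass
class ActivityRecord:
    """One individual's minute-resolution activity plus schedule and metadata.

    ``alive_until`` is the exclusive minute index up to which the animal is
    considered alive; analyses use ``counts[:alive_until]`` only.
    """

    individual_id: str
    counts: np.ndarray
    schedule: LightSchedule
    meta: IndividualMeta = field(default_factory=IndividualMeta)
    alive_until: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be 1-D")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(self.counts) != self.schedule.total_minutes:
            raise ValueError(
                f"{self.individual_id}: series length {len(self.counts)} != "
                f"schedule duration {self.schedule.total_minutes}"
            )
        if self.alive_until is None:
            self.alive_until = len(self.counts)
        if not (0 <= self.alive_until <= len(self.counts)):
            raise ValueError("alive_until outside series")

    @property
    def alive_counts(self) -> np.ndarray:
        return self.counts[: self.alive_until]


def attach_metadata(monitor: MonitorFile, channel_map: pd.DataFrame,
                    schedule: LightSchedule) -> list[ActivityRecord]:
    """Turn mapped monitor channels into ActivityRecords.

    ``channel_map`` needs columns ``individual_id, channel`` and optionally
    ``population, latitude, line, sex, mating`` (and ``monitor``, in which
    case only rows matching this monitor's id are used).  Channels are
    1-based.  Unmapped channels are ignored with a logged notice.
    """
    cm = channel_map
    if "monitor" in cm.columns:
        cm = cm[cm["monitor"].astype(str) == str(monitor.monitor_id)]
    if cm["individual_id"].duplicated().any():
        dups = cm.loc[cm["individual_id"].duplicated(), "individual_id"].tolist()
        raise ValueError(f"duplicate individual_id in channel map: {dups}")
    if cm["channel"].duplicated().any():
        raise ValueError("duplicate channel in channel map")

    n_min = monitor.n_rows
    if n_min != schedule.total_minutes:
        raise ValueError(
            f"monitor {monitor.monitor_id} has {n_min} rows but schedule spans "
            f"{schedule.total_minutes} minutes"
        )

    records = []
    for _, row in cm.iterrows():
        ch = int(row["channel"])
        if not (1 <= ch <= N_CHANNELS):
            raise ValueError(f"channel {ch} outside 1..{N_CHANNELS}")
        meta = IndividualMeta(
            population=str(row.get("population", "")),
            latitude=float(row.get("latitude", float("nan"))),
            line=str(row.get("line", "")),
            sex=str(row.get("sex", "F")),
            mating=str(row.get("mating", "virgin")),
        )
        records.append(
            ActivityRecord(
                individual_id=str(row["individual_id"]),
                counts=monitor.counts[:, ch - 1].copy(),
                schedule=schedule,
                meta=meta,
            )
        )
    unmapped = N_CHANNELS - len(cm)
    if unmapped:
        logger.info("monitor %s: %d unmapped channels ignored",
                    monitor.monitor_id, unmapped)
    return records


def mark_dead(record: ActivityRecord, quiet_hours: float = 24.0) -> ActivityRecord:
    """Flag a terminal all-zero run of at least ``quiet_hours`` as death.

    Returns a copy with ``alive_until`` set to the start of the terminal zero
    run when that run is long enough; otherwise the record is returned
    unchanged.  Idempotent, and never moves ``alive_until`` later.
    """
    counts = record.alive_counts
    if len(counts) == 0:
        return record
    nz = np.flatnonzero(counts)
    run_start = 0 if len(nz) == 0 else int(nz[-1]) + 1
    tail = len(counts) - run_start
    if tail >= quiet_hours * 60:
        return replace(record, alive_until=run_start)
    return record


def is_excluded_dead(record: ActivityRecord, analysis_start: int = 0,
                     min_days: int = 2) -> bool:
    """True if the animal died before completing ``min_days`` full days of the
    analysed segment beginning at ``analysis_start`` (such records are dropped
    from all analyses, mirroring the omission of dead animals)."""
    return (record.alive_until - analysis_start) < min_days * MINUTES_PER_DAY


@dataclass
class BinnedSeries:
    """Counts summed into fixed-width bins aligned to ZT 0.

    ``start_minute`` is the schedule minute of the first bin's left edge and
    must itself be bin-aligned so bins line up with Zeitgeber time.
    """

    bin_minutes: int
    values: np.ndarray
    start_minute: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if MINUTES_PER_DAY % self.bin_minutes != 0:
            raise ValueError(f"bin_minutes {self.bin_minutes} must divide 1440")

    @property
    def bins_per_day(self) -> int:
        return MINUTES_PER_DAY // self.bin_minutes

    def zt_bin_starts(self) -> np.ndarray:
        """ZT (h) of each bin's left edge."""
        starts = self.start_minute + self.bin_minutes * np.arange(len(self.values))
        return (starts / 60.0) % 24.0


def bin_counts(record: ActivityRecord, bin_minutes: int,
               start_minute: int = 0, stop_minute: int | None = None) -> BinnedSeries:
    """Sum minute counts into ``bin_minutes`` bins over [start, stop).

    Bins are aligned to ZT 0: ``start_minute`` must be a multiple of
    ``bin_minutes``.  The span is clipped to ``alive_until`` and a trailing
    partial bin is dropped, so totals are conserved over whole bins.
    """
    if MINUTES_PER_DAY % bin_minutes != 0:
        raise ValueError(f"bin_minutes {bin_minutes} must divide 1440")
    if start_minute % bin_minutes != 0:
        raise ValueError("start_minute must be bin-aligned")
    stop = record.alive_until if stop_minute is None else min(stop_minute, record.alive_until)
    seg = record.counts[start_minute:stop]
    n_bins = len(seg) // bin_minutes
    seg = seg[: n_bins * bin_minutes]
    values = seg.reshape(n_bins, bin_minutes).sum(axis=1)
    return BinnedSeries(bin_minutes=bin_minutes, values=values, start_minute=start_minute)
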