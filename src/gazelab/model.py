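"""In-memory model of a wearable eye-tracking recording.

A recording is a bundle of parallel time-stamped streams sharing one
session clock: raw gaze samples, detected fixations / blinks / saccades,
pupillometry (eye-state) samples, experiment events, and the
surface-mapped ("enriched") gaze and fixation streams that carry ROI
membership.  Each stream is held as a :class:`pandas.DataFrame` with
canonical column names; timestamps are 64-bit integer nanoseconds so
that all interval logic is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

NS_PER_MS = 1_000_000
NS_PER_S = 1_000_000_000

#: canonical columns per stream (internal names, not the CSV dialect)
GAZE_COLUMNS = ["timestamp", "x", "y", "worn", "fixation_id", "blink_id"]
FIXATION_COLUMNS = ["id", "start_ts", "end_ts", "duration_ms", "cx", "cy"]
BLINK_COLUMNS = ["id", "start_ts", "end_ts", "duration_ms"]
SACCADE_COLUMNS = [
    "id", "start_ts", "end_ts", "duration_ms",
    "amplitude_px", "mean_velocity", "peak_velocity",
]
PUPIL_COLUMNS = ["timestamp", "diameter_left", "diameter_right", "diameter"]
EVENT_COLUMNS = ["name", "timestamp"]
SURFACE_COLUMNS = ["timestamp", "on_surface", "sx", "sy"]

_STREAM_COLUMNS = {
    "gaze": GAZE_COLUMNS,
    "fixations": FIXATION_COLUMNS,
    "blinks": BLINK_COLUMNS,
    "saccades": SACCADE_COLUMNS,
    "pupil": PUPIL_COLUMNS,
    "events": EVENT_COLUMNS,
    "surface_gaze": SURFACE_COLUMNS,
    "surface_fixations": SURFACE_COLUMNS,
}

_INT_LIKE = {"timestamp", "start_ts", "end_ts"}
_NULLABLE_INT = {"fixation_id", "blink_id", "id"}


def empty_stream(name: str) -> pd.DataFrame:
    """Typed, zero-row frame with the canonical columns of *name*."""
    cols = _STREAM_COLUMNS[name]
    data = {}
    for c in cols:
        if c in _INT_LIKE:
            data[c] = pd.Series([], dtype="int64")
        elif c in _NULLABLE_INT:
            data[c] = pd.Series([], dtype="Int64")
        elif c in ("worn", "on_surface"):
            data[c] = pd.Series([], dtype="bool")
        elif c == "name":
            data[c] = pd.Series([], dtype="object")
        else:
            data[c] = pd.Series([], dtype="float64")
    return pd.DataFrame(data)


@dataclass(frozen=True)
class Epoch:
    """A named half-open time window ``[start_ts, end_ts)`` in session ns."""

    name: str
    start_ts: int
    end_ts: int

    def __post_init__(self) -> None:
        if self.end_ts <= self.start_ts:
            raise ValueError(
                f"epoch {self.name!r}: end_ts ({self.end_ts}) must exceed "
                f"start_ts ({self.start_ts})"
            )

    @property
    def duration_ms(self) -> float:
        return (self.end_ts - self.start_ts) / NS_PER_MS

    @property
    def duration_s(self) -> float:
        return (self.end_ts - self.start_ts) / NS_PER_S

    def contains(self, t: int) -> bool:
        return self.start_ts <= t < self.end_ts


@dataclass(frozen=True)
class Issue:
    """One machine-readable validation finding."""

    stream: str
    kind: str
    message: str
    ids: tuple = ()


@dataclass
class Recording:
    """All streams of one session, sorted by timestamp, on one clock."""

    gaze: pd.DataFrame = field(default_factory=lambda: empty_stream("gaze"))
    fixations: pd.DataFrame = field(default_factory=lambda: empty_stream("fixations"))
    blinks: pd.DataFrame = field(default_factory=lambda: empty_stream("blinks"))
    saccades: pd.DataFrame = field(default_factory=lambda: empty_stream("saccades"))
    pupil: pd.DataFrame = field(default_factory=lambda: empty_stream("pupil"))
    events: pd.DataFrame = field(default_factory=lambda: empty_stream("events"))
    surface_gaze: pd.DataFrame = field(default_factory=lambda: empty_stream("surface_gaze"))
    surface_fixations: pd.DataFrame = field(default_factory=lambda: empty_stream("surface_fixations"))
    participant: str = ""

    _POINT_STREAMS = ("gaze", "pupil", "surface_gaze", "surface_fixations")
    _INTERVAL_STREAMS = ("fixations", "blinks", "saccades")

    def streams(self) -> Iterator[tuple[str, pd.DataFrame]]:
        for name in _STREAM_COLUMNS:
            yield name, getattr(self, name)

    def span(self) -> tuple[int, int]:
        """(earliest, latest) timestamp over every stream; latest is exclusive-ish
        in the sense that interval streams contribute their end timestamps."""
        starts: list[int] = []
        ends: list[int] = []
        for name, df in self.streams():
            if df.empty:
                continue
            if "timestamp" in df.columns:
                starts.append(int(df["timestamp"].iloc[0]))
                ends.append(int(df["timestamp"].iloc[-1]))
            else:
                starts.append(int(df["start_ts"].min()))
                ends.append(int(df["end_ts"].max()))
        if not starts:
            raise ValueError("recording is empty; span undefined")
        return min(starts), max(ends)

    def copy(self) -> "Recording":
        return replace(
            self,
            **{name: df.copy() for name, df in self.streams()},
        )


def ensure_sorted(df: pd.DataFrame, by: str) -> pd.DataFrame:
    """Stable-sort *df* by column *by* (no-op when already ordered)."""
    if df.empty or df[by].is_monotonic_increasing:
        return df.reset_index(drop=True)
    return df.sort_values(by, kind="stable").reset_index(drop=True)


def recompute_duration_ms(df: pd.DataFrame) -> np.ndarray:
    """Interval duration from timestamps, in ms (float)."""
    return (df["end_ts"].to_numpy() - df["start_ts"].to_numpy()) / NS_PER_MS
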