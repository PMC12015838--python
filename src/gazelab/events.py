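"""Event handling and epoching.

Experiment events partition the session timeline into named epochs.
Every event except the last opens an epoch that runs until the next
event's timestamp; the final event is a pure terminator.  Epochs are
half-open ``[t_i, t_{i+1})`` so that they tile the analysed span with
no gap and no overlap.  A recording whose event stream holds only a
start and an end event therefore yields a single epoch covering the
whole recording.

The cloud event stream can be replaced wholesale by a user-supplied
event table — the route for aligning epochs to an external device.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path

import pandas as pd

from .io import RecordingError, normalise_header
from .model import Epoch, Recording, empty_stream

logger = logging.getLogger(__name__)


def load_event_file(path: str | Path) -> pd.DataFrame:
    """Read a delimited event table (columns: name, timestamp in ns).

    Rows are stable-sorted by timestamp, so simultaneous events keep
    their file order.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    rename = {}
    for col in raw.columns:
        key = normalise_header(col)
        if key in ("name", "event", "label"):
            rename[col] = "name"
        elif key in ("timestamp", "time"):
            rename[col] = "timestamp"
    raw = raw.rename(columns=rename)
    if "name" not in raw.columns or "timestamp" not in raw.columns:
        raise RecordingError(
            f"{path.name}: event file needs 'name' and 'timestamp [ns]' columns"
        )
    events = empty_stream("events")
    if len(raw) == 0:
        raise RecordingError(f"{path.name}: event file is empty")
    ts = pd.to_numeric(raw["timestamp"], errors="coerce")
    bad = ts.isna() | (raw["name"].astype(str).str.len() == 0)
    if bad.any():
        logger.warning("%s: skipped %d malformed event row(s)", path.name, int(bad.sum()))
    out = pd.DataFrame({
        "name": raw.loc[~bad, "name"].astype(str),
        "timestamp": ts[~bad].round().astype("int64"),
    })
    if out.empty:
        raise RecordingError(f"{path.name}: no parseable event rows")
    out = out.sort_values("timestamp", kind="stable").reset_index(drop=True)
    return pd.concat([events, out], ignore_index=True) if events.empty else out


def replace_events(rec: Recording, events: pd.DataFrame) -> Recording:
    """Return a recording whose event stream is exactly *events*.

    All other streams are untouched.  It is fatal for every supplied
    event to fall outside the recording's span — that indicates clocks
    that were never aligned.
    """
    if events is None or len(events) == 0:
        raise RecordingError("replacement event table is empty")
    start, end = rec.span()
    ts = events["timestamp"]
    if (ts.max() < start) or (ts.min() > end):
        raise RecordingError(
            "replacement events lie entirely outside the recording span "
            f"[{start}, {end}] ns (events cover [{int(ts.min())}, {int(ts.max())}] ns); "
            "check clock alignment"
        )
    new_events = events.sort_values("timestamp", kind="stable").reset_index(drop=True)
    return replace(rec, events=new_events[["name", "timestamp"]].copy())


def build_epochs(events: pd.DataFrame,
                 span: tuple[int, int] | None = None) -> list[Epoch]:
    """Chain consecutive events into named half-open epochs.

    ``n`` events yield ``n - 1`` epochs; epoch *i* is named after event
    *i* and spans ``[t_i, t_{i+1})``.  Zero-length epochs (duplicate
    timestamps) are dropped with a warning so the tiling stays exact.
    *span* is informational only: when given, events outside it trigger
    a warning.
    """
    if events is None or len(events) < 2:
        raise RecordingError("at least two events (a start and an end) are "
                             "needed to build epochs")
    ev = events.sort_values("timestamp", kind="stable").reset_index(drop=True)
    if span is not None:
        lo, hi = span
        outside = (ev["timestamp"] < lo) | (ev["timestamp"] > hi)
        if outside.any():
            logger.warning("%d event(s) fall outside the recording span",
                           int(outside.sum()))
    epochs: list[Epoch] = []
    names = ev["name"].tolist()
    times = ev["timestamp"].astype("int64").tolist()
    for i in range(len(ev) - 1):
        if times[i + 1] == times[i]:
            logger.warning("event %r at %d opens a zero-length epoch; dropped",
                           names[i], times[i])
            continue
        epochs.append(Epoch(name=str(names[i]), start_ts=times[i], end_ts=times[i + 1]))
    return epochs


def _midpoints(df: pd.DataFrame) -> pd.Series:
    # integer midpoint: exact, no float drift
    return (df["start_ts"] + df["end_ts"]) // 2


def slice_recording(rec: Recording, epoch: Epoch) -> Recording:
    """Restrict every stream of *rec* to *epoch*.

    Point-sample streams (gaze, pupil, surface) keep samples with
    ``start_ts <= t < end_ts``.  Interval streams (fixations, blinks,
    saccades) are assigned whole to the epoch containing their midpoint,
    so straddling intervals are never split and per-epoch counts are
    conserved across a partition.
    """
    out = {}
    for name, df in rec.streams():
        if df.empty:
            out[name] = df.copy()
        elif "timestamp" in df.columns:
            mask = (df["timestamp"] >= epoch.start_ts) & (df["timestamp"] < epoch.end_ts)
            out[name] = df[mask].reset_index(drop=True)
        else:
            mid = _midpoints(df)
            mask = (mid >= epoch.start_ts) & (mid < epoch.end_ts)
            out[name] = df[mask].reset_index(drop=True)
    sliced = replace(rec, **out)
    if all(df.empty for _, df in sliced.streams()):
        logger.info("epoch %r contains no samples", epoch.name)
    return sliced
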