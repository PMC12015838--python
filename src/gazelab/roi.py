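"""ROI (area-of-interest) gating from the surface-enrichment stream.

The enrichment stream carries, for each mapped gaze sample, a boolean
"detected on surface" flag plus surface-normalised coordinates.  This
module propagates that flag onto the other streams:

* gaze and pupil samples take the flag of the temporally nearest
  surface sample, within a matching tolerance (default 25 ms, about
  five nominal sample periods at 200 Hz);
* saccades take a majority vote of the surface samples overlapping the
  saccade interval (ties resolved by the status at onset) — gaze is
  valid throughout a saccade;
* blinks take the status of the last surface sample at or before the
  blink onset (lookback <= 200 ms), falling back to the first sample at
  or after the offset (lookahead <= 200 ms) — gaze is absent while the
  lid is closed, so the flag must come from the shoulders.

Samples with no surface sample in tolerance default to off-ROI (0 /
False), never missing, so downstream sums stay well-defined; each such
default is logged.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .io import RecordingError
from .model import NS_PER_MS, Recording

logger = logging.getLogger(__name__)

GAZE_TOLERANCE_MS = 25.0     #: nearest-sample match window for gaze/pupil
BLINK_LOOKBACK_MS = 200.0    #: shoulder search window around a blink


def _nearest_surface_flags(timestamps: np.ndarray, surface: pd.DataFrame,
                           tolerance_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """(on_surface flag, matched?) of the nearest surface sample per query."""
    sts = surface["timestamp"].to_numpy(dtype="int64")
    sflag = surface["on_surface"].to_numpy(dtype=bool)
    tol = int(tolerance_ms * NS_PER_MS)

    idx = np.searchsorted(sts, timestamps)
    left = np.clip(idx - 1, 0, len(sts) - 1)
    right = np.clip(idx, 0, len(sts) - 1)
    d_left = np.abs(timestamps - sts[left])
    d_right = np.abs(sts[right] - timestamps)
    take_right = d_right < d_left
    nearest = np.where(take_right, right, left)
    dist = np.where(take_right, d_right, d_left)
    matched = dist <= tol
    flags = np.where(matched, sflag[nearest], False)
    return flags, matched


def annotate_gaze_on_roi(gaze: pd.DataFrame, surface_gaze: pd.DataFrame,
                         tolerance_ms: float = GAZE_TOLERANCE_MS) -> np.ndarray:
    """Per-gaze-frame binary ROI membership (1 on-ROI, 0 off)."""
    if surface_gaze is None or surface_gaze.empty:
        raise RecordingError("ROI annotation needs a non-empty surface "
                             "enrichment stream (required in this version)")
    if gaze.empty:
        return np.zeros(0, dtype="int64")
    flags, matched = _nearest_surface_flags(
        gaze["timestamp"].to_numpy(dtype="int64"), surface_gaze, tolerance_ms)
    n_gap = int((~matched).sum())
    if n_gap:
        logger.warning("%d gaze frame(s) had no surface sample within %.0f ms; "
                       "defaulted to off-ROI", n_gap, tolerance_ms)
    return flags.astype("int64")


def annotate_pupil_on_roi(pupil: pd.DataFrame, surface_gaze: pd.DataFrame,
                          tolerance_ms: float = GAZE_TOLERANCE_MS) -> np.ndarray:
    """Per-pupil-sample ROI membership, as booleans (True/False)."""
    if pupil.empty:
        return np.zeros(0, dtype=bool)
    if surface_gaze is None or surface_gaze.empty:
        raise RecordingError("ROI annotation needs a non-empty surface "
                             "enrichment stream (required in this version)")
    flags, matched = _nearest_surface_flags(
        pupil["timestamp"].to_numpy(dtype="int64"), surface_gaze, tolerance_ms)
    n_gap = int((~matched).sum())
    if n_gap:
        logger.warning("%d pupil sample(s) unmatched within %.0f ms; "
                       "defaulted to off-ROI", n_gap, tolerance_ms)
    return flags.astype(bool)


def annotate_intervals_on_roi(intervals: pd.DataFrame, surface_gaze: pd.DataFrame,
                              kind: str,
                              lookback_ms: float = BLINK_LOOKBACK_MS) -> np.ndarray:
    """ROI membership for interval events (*kind* ``"blink"`` or ``"saccade"``)."""
    if kind not in ("blink", "saccade"):
        raise ValueError(f"unknown interval kind {kind!r}")
    if intervals.empty:
        return np.zeros(0, dtype=bool)
    if surface_gaze is None or surface_gaze.empty:
        raise RecordingError("ROI annotation needs a non-empty surface stream")

    sts = surface_gaze["timestamp"].to_numpy(dtype="int64")
    sflag = surface_gaze["on_surface"].to_numpy(dtype=bool)
    starts = intervals["start_ts"].to_numpy(dtype="int64")
    ends = intervals["end_ts"].to_numpy(dtype="int64")
    out = np.zeros(len(intervals), dtype=bool)

    if kind == "saccade":
        lo = np.searchsorted(sts, starts, side="left")
        hi = np.searchsorted(sts, ends, side="left")
        cum = np.concatenate([[0], np.cumsum(sflag)])
        n_on = cum[hi] - cum[lo]
        n_all = hi - lo
        majority = n_on * 2 > n_all
        tie = n_on * 2 == n_all  # includes the empty-overlap case
        out = majority.copy()
        if tie.any():
            onset_flags, onset_ok = _nearest_surface_flags(
                starts[tie], surface_gaze, lookback_ms)
            out[tie] = np.where(onset_ok, onset_flags, False)
        return out

    # blinks: shoulder rule
    before = np.searchsorted(sts, starts, side="right") - 1
    after = np.searchsorted(sts, ends, side="left")
    look = int(lookback_ms * NS_PER_MS)
    n_default = 0
    for i in range(len(intervals)):
        b = before[i]
        if b >= 0 and starts[i] - sts[b] <= look:
            out[i] = sflag[b]
            continue
        a = after[i]
        if a < len(sts) and sts[a] - ends[i] <= look:
            out[i] = sflag[a]
            continue
        out[i] = False
        n_default += 1
    if n_default:
        logger.warning("%d blink(s) isolated by more than %.0f ms from any "
                       "surface sample; defaulted to off-ROI", n_default, lookback_ms)
    return out


def annotate_recording(rec: Recording,
                       tolerance_ms: float = GAZE_TOLERANCE_MS,
                       lookback_ms: float = BLINK_LOOKBACK_MS) -> Recording:
    """Return a copy of *rec* with ``on_roi`` columns on gaze, pupil,
    blinks, and saccades.  Counts, timestamps, and durations are never
    touched — only flags are added."""
    gaze = rec.gaze.copy()
    gaze["on_roi"] = annotate_gaze_on_roi(rec.gaze, rec.surface_gaze, tolerance_ms)
    pupil = rec.pupil.copy()
    pupil["on_roi"] = annotate_pupil_on_roi(rec.pupil, rec.surface_gaze, tolerance_ms)
    blinks = rec.blinks.copy()
    blinks["on_roi"] = annotate_intervals_on_roi(rec.blinks, rec.surface_gaze,
                                                 "blink", lookback_ms)
    saccades = rec.saccades.copy()
    saccades["on_roi"] = annotate_intervals_on_roi(rec.saccades, rec.surface_gaze,
                                                   "saccade", lookback_ms)
    return replace(rec, gaze=gaze, pupil=pupil, blinks=blinks, saccades=saccades)


def roi_occupancy_fraction(flags) -> float:
    """Mean of a binary on-ROI flag sequence."""
    arr = np.asarray(flags, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot compute an occupancy fraction of an empty "
                         "flag sequence")
    return float(arr.mean())
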