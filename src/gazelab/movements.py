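"""Inter-fixation gaze movements and per-fixation gaze groups.

Fixation detection is the device's job: gaze samples arrive already
labelled with a fixation id (and a blink id while the lid is closed).
This module only *segments*: the ordered run of unlabelled samples
strictly between the last sample of fixation *k* and the first sample
of fixation *k+1* is movement *k* — the transition path the eye took
between the two fixations.  Samples before the first or after the last
fixation belong to no movement, and samples inside a blink are excluded
(lid-closed gaze is noise).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MOVEMENT_COLUMNS = ["id", "n_samples", "duration_ms", "path_length", "displacement"]


def index_movements(gaze: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of *gaze* with a nullable ``movement_id`` column.

    ``movement_id`` equals the id of the preceding fixation for every
    sample that lies between two fixations and carries neither a
    fixation id nor a blink id.
    """
    out = gaze.copy()
    fid = out["fixation_id"]
    if fid.notna().sum() == 0:
        logger.warning("gaze stream has no fixation labels; no movements indexed")
        out["movement_id"] = pd.Series([pd.NA] * len(out), dtype="Int64")
        return out
    prev_fix = fid.ffill()
    next_fix = fid.bfill()
    between = fid.isna() & prev_fix.notna() & next_fix.notna()
    in_blink = out["blink_id"].notna() if "blink_id" in out.columns else False
    member = between & ~in_blink
    movement_id = pd.Series([pd.NA] * len(out), dtype="Int64")
    movement_id[member] = prev_fix[member].astype("Int64")
    out["movement_id"] = movement_id
    return out


def path_metrics(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(path_length, displacement) of an ordered 2-D sample run."""
    if len(x) < 2:
        return 0.0, 0.0
    steps = np.hypot(np.diff(x), np.diff(y))
    path = float(steps.sum())
    disp = float(np.hypot(x[-1] - x[0], y[-1] - y[0]))
    return path, disp


def extract_movements(indexed_gaze: pd.DataFrame,
                      x: str = "x", y: str = "y") -> pd.DataFrame:
    """One row per movement: sample count, duration, path length (sum of
    consecutive Euclidean steps), and displacement (first-to-last).

    Coordinate columns are selectable so the same extraction serves both
    scene-pixel (absolute) and surface-normalised (relative) coordinates.
    Rows whose coordinate values are missing are dropped from the run.
    """
    if "movement_id" not in indexed_gaze.columns:
        raise ValueError("gaze stream has no movement ids; run index_movements first")
    rows = []
    labelled = indexed_gaze[indexed_gaze["movement_id"].notna()]
    for mid, grp in labelled.groupby("movement_id", sort=True):
        grp = grp.dropna(subset=[x, y])
        if grp.empty:
            continue
        ts = grp["timestamp"].to_numpy(dtype="int64")
        path, disp = path_metrics(grp[x].to_numpy(dtype=float),
                                  grp[y].to_numpy(dtype=float))
        rows.append({
            "id": int(mid),
            "n_samples": len(grp),
            "duration_ms": float((ts[-1] - ts[0]) / 1e6),
            "path_length": path,
            "displacement": disp,
        })
    if not rows:
        return pd.DataFrame(columns=MOVEMENT_COLUMNS)
    return pd.DataFrame(rows, columns=MOVEMENT_COLUMNS)


def collect_gaze_groups(gaze: pd.DataFrame, by: str = "fixation"
                        ) -> dict[int, pd.DataFrame]:
    """Ordered gaze-sample runs keyed by fixation or movement id.

    Every sample appears in at most one group; group sizes feed the
    per-fixation / per-movement gaze counts.
    """
    if by == "fixation":
        key = "fixation_id"
    elif by == "movement":
        key = "movement_id"
        if key not in gaze.columns:
            raise ValueError("run index_movements before grouping by movement")
    else:
        raise ValueError(f"unknown grouping {by!r} (use 'fixation' or 'movement')")
    labelled = gaze[gaze[key].notna()]
    return {int(k): g.reset_index(drop=True)
            for k, g in labelled.groupby(key, sort=True)}
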