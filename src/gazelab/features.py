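"""Per-epoch feature battery and the basic statistics on top of it.

For every epoch the five stream categories (blink, fixation, gaze,
saccade, pupillometry) are summarised into a tidy table of named
indices, each carrying its unit.  Descriptive statistics use the
population standard deviation (divisor = count) throughout — that is
the contract of the summary-equation set this pipeline implements.

Empty categories yield explicit empty markers (NaN), not zeros, except
counts, which are genuinely zero: "no saccades" is distinct from
"saccades of zero amplitude".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import Epoch, Recording
from .movements import collect_gaze_groups, extract_movements, index_movements

CATEGORIES = ("blink", "fixation", "gaze", "saccade", "pupil")

DEFAULT_BLINK_THRESHOLD = 5  #: epochs with strictly more blinks are excluded


# ---------------------------------------------------------------- primitives

@dataclass(frozen=True)
class Point2D:
    """A 2-D point tagged with its coordinate frame ('px' or 'norm')."""
    x: float
    y: float
    frame: str = "px"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("Point2D coordinates must be finite")


def euclidean_distance(p1: Point2D, p2: Point2D) -> float:
    """Straight-line distance between two points in the same frame."""
    if p1.frame != p2.frame:
        raise ValueError(
            f"cannot measure a distance across coordinate frames "
            f"({p1.frame!r} vs {p2.frame!r})"
        )
    return math.hypot(p2.x - p1.x, p2.y - p1.y)


@dataclass(frozen=True)
class DescriptiveStats:
    """max / min / sum / count / mean / population std of a value list."""
    maximum: float
    minimum: float
    total: float
    count: int
    mean: float
    std: float


def descriptive_stats(values) -> DescriptiveStats:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("descriptive statistics of an empty list are undefined")
    mean = float(arr.mean())
    # population form: divisor = count
    std = float(np.sqrt(np.mean((arr - mean) ** 2)))
    return DescriptiveStats(
        maximum=float(arr.max()), minimum=float(arr.min()),
        total=float(arr.sum()), count=int(arr.size), mean=mean, std=std,
    )


# ------------------------------------------------------------ report object

@dataclass
class FeatureReport:
    """Tidy per-epoch feature table plus any attached statistics."""

    participant: str
    table: pd.DataFrame  # columns: epoch, category, index, value, units
    stats: dict = field(default_factory=dict)
    exclusions: list = field(default_factory=list)

    def value(self, epoch: str, category: str, index: str) -> float:
        t = self.table
        row = t[(t["epoch"] == epoch) & (t["category"] == category)
                & (t["index"] == index)]
        if row.empty:
            raise KeyError(f"no index {index!r} for epoch {epoch!r} / {category!r}")
        return float(row["value"].iloc[0])

    def epochs(self) -> list[str]:
        return list(dict.fromkeys(self.table["epoch"]))

    def to_text(self) -> str:
        lines = [f"Participant: {self.participant}", ""]
        for epoch in self.epochs():
            lines.append(f"== Epoch: {epoch} ==")
            sub = self.table[self.table["epoch"] == epoch]
            for cat in dict.fromkeys(sub["category"]):
                lines.append(f"  [{cat}]")
                for _, r in sub[sub["category"] == cat].iterrows():
                    v = r["value"]
                    sval = "(empty)" if pd.isna(v) else f"{v:.6g}"
                    unit = f" {r['units']}" if r["units"] else ""
                    lines.append(f"    {r['index']}: {sval}{unit}")
            lines.append("")
        if self.exclusions:
            lines.append("Excluded epochs (blink filter):")
            for name, count in self.exclusions:
                lines.append(f"  {name}: {count} blinks")
            lines.append("")
        for key, val in self.stats.items():
            lines.append(f"{key}: {val}")
        return "\n".join(lines) + "\n"


# ------------------------------------------------------- category extractors

def _stats_or_nan(values) -> DescriptiveStats | None:
    vals = [v for v in values if v is not None and np.isfinite(v)]
    return descriptive_stats(vals) if vals else None


def blink_features(sl: Recording) -> dict[str, float]:
    """Count and durations (total / average / on-ROI total), ms."""
    df = sl.blinks
    if "on_roi" not in df.columns:
        raise ValueError("blink stream is not ROI-annotated")
    if df.empty:
        return {"count": 0, "duration_total_ms": 0.0,
                "duration_mean_ms": 0.0, "duration_on_roi_ms": 0.0}
    dur = df["duration_ms"].to_numpy(dtype=float)
    on = df["on_roi"].to_numpy(dtype=bool)
    return {
        "count": int(len(df)),
        "duration_total_ms": float(dur.sum()),
        "duration_mean_ms": float(dur.mean()),
        "duration_on_roi_ms": float(dur[on].sum()),
    }


def fixation_features(sl: Recording) -> dict[str, float]:
    """Durations, centroid positions, and consecutive-centroid distances.

    Distances are reported both in scene pixels (absolute) and, when the
    surface-fixation enrichment provides normalised centroids, in
    surface units (relative).
    """
    df = sl.fixations
    out: dict[str, float] = {"count": int(len(df))}
    nan_keys = ["duration_total_ms", "duration_mean_ms", "duration_max_ms",
                "duration_min_ms", "longest_x_px", "longest_y_px",
                "mean_x_px", "mean_y_px",
                "distance_total_px", "distance_mean_px",
                "distance_total_rel", "distance_mean_rel"]
    for k in nan_keys:
        out[k] = float("nan")
    if df.empty:
        return out

    ds = descriptive_stats(df["duration_ms"])
    out.update(duration_total_ms=ds.total, duration_mean_ms=ds.mean,
               duration_max_ms=ds.maximum, duration_min_ms=ds.minimum)
    longest = df.iloc[int(np.argmax(df["duration_ms"].to_numpy()))]
    out["longest_x_px"] = float(longest["cx"])
    out["longest_y_px"] = float(longest["cy"])
    out["mean_x_px"] = float(df["cx"].mean())
    out["mean_y_px"] = float(df["cy"].mean())

    if len(df) >= 2:
        steps = np.hypot(np.diff(df["cx"].to_numpy(dtype=float)),
                         np.diff(df["cy"].to_numpy(dtype=float)))
        out["distance_total_px"] = float(steps.sum())
        out["distance_mean_px"] = float(steps.mean())
        rel = _relative_fixation_coords(sl)
        if rel is not None and len(rel) >= 2:
            rsteps = np.hypot(np.diff(rel[:, 0]), np.diff(rel[:, 1]))
            out["distance_total_rel"] = float(rsteps.sum())
            out["distance_mean_rel"] = float(rsteps.mean())
    return out


def _relative_fixation_coords(sl: Recording) -> np.ndarray | None:
    """Surface-normalised fixation centroids matched by start timestamp."""
    sf = sl.surface_fixations
    if sf.empty or sl.fixations.empty:
        return None
    sts = sf["timestamp"].to_numpy(dtype="int64")
    starts = sl.fixations["start_ts"].to_numpy(dtype="int64")
    idx = np.searchsorted(sts, starts)
    left = np.clip(idx - 1, 0, len(sts) - 1)
    right = np.clip(idx, 0, len(sts) - 1)
    nearest = np.where(np.abs(sts[right] - starts) < np.abs(starts - sts[left]),
                       right, left)
    coords = sf.iloc[nearest][["sx", "sy"]].to_numpy(dtype=float)
    if np.isnan(coords).all():
        return None
    return coords


def attach_surface_coords(gaze: pd.DataFrame, surface_gaze: pd.DataFrame,
                          tolerance_ms: float = 25.0) -> pd.DataFrame:
    """Copy of *gaze* with nearest-matched surface coordinates sx, sy."""
    out = gaze.copy()
    if surface_gaze.empty or gaze.empty:
        out["sx"] = np.nan
        out["sy"] = np.nan
        return out
    sts = surface_gaze["timestamp"].to_numpy(dtype="int64")
    ts = gaze["timestamp"].to_numpy(dtype="int64")
    idx = np.searchsorted(sts, ts)
    left = np.clip(idx - 1, 0, len(sts) - 1)
    right = np.clip(idx, 0, len(sts) - 1)
    nearest = np.where(np.abs(sts[right] - ts) < np.abs(ts - sts[left]), right, left)
    dist = np.abs(sts[nearest] - ts)
    ok = dist <= int(tolerance_ms * 1e6)
    sx = surface_gaze["sx"].to_numpy(dtype=float)[nearest]
    sy = surface_gaze["sy"].to_numpy(dtype=float)[nearest]
    out["sx"] = np.where(ok, sx, np.nan)
    out["sy"] = np.where(ok, sy, np.nan)
    return out


def gaze_features(sl: Recording) -> dict[str, float]:
    """Sample counts and inter-fixation movement metrics.

    Movement distances (path lengths) are reported in scene pixels
    (absolute) and surface units (relative).
    """
    gaze = sl.gaze
    if "movement_id" not in gaze.columns:
        gaze = index_movements(gaze)
    out: dict[str, float] = {"sample_count": int(len(gaze))}
    nan_keys = ["samples_per_fixation_mean", "samples_per_movement_mean",
                "movement_count",
                "movement_duration_total_ms", "movement_duration_mean_ms",
                "movement_distance_total_px", "movement_distance_mean_px",
                "movement_distance_max_px", "movement_distance_min_px",
                "movement_distance_total_rel", "movement_distance_mean_rel",
                "movement_distance_max_rel", "movement_distance_min_rel"]
    for k in nan_keys:
        out[k] = float("nan")
    out["movement_count"] = 0

    fix_groups = collect_gaze_groups(gaze, by="fixation")
    if fix_groups:
        out["samples_per_fixation_mean"] = float(
            np.mean([len(g) for g in fix_groups.values()]))
    mov_groups = collect_gaze_groups(gaze, by="movement")
    if mov_groups:
        out["samples_per_movement_mean"] = float(
            np.mean([len(g) for g in mov_groups.values()]))

    movements = extract_movements(gaze)
    out["movement_count"] = int(len(movements))
    if movements.empty:
        return out
    out["movement_duration_total_ms"] = float(movements["duration_ms"].sum())
    out["movement_duration_mean_ms"] = float(movements["duration_ms"].mean())
    d = descriptive_stats(movements["path_length"])
    out.update(movement_distance_total_px=d.total, movement_distance_mean_px=d.mean,
               movement_distance_max_px=d.maximum, movement_distance_min_px=d.minimum)

    rel_gaze = attach_surface_coords(gaze, sl.surface_gaze)
    rel_movs = extract_movements(rel_gaze, x="sx", y="sy")
    if not rel_movs.empty:
        d = descriptive_stats(rel_movs["path_length"])
        out.update(movement_distance_total_rel=d.total,
                   movement_distance_mean_rel=d.mean,
                   movement_distance_max_rel=d.maximum,
                   movement_distance_min_rel=d.minimum)
    return out


def saccade_features(sl: Recording) -> dict[str, float]:
    """Durations, amplitudes, and velocities of the saccade inventory."""
    df = sl.saccades
    out: dict[str, float] = {"count": int(len(df))}
    nan_keys = ["duration_total_ms", "duration_mean_ms", "duration_max_ms",
                "duration_min_ms", "amplitude_mean_px", "amplitude_max_px",
                "amplitude_min_px", "velocity_mean_px_s", "velocity_max_px_s",
                "velocity_min_px_s", "peak_velocity_px_s"]
    for k in nan_keys:
        out[k] = float("nan")
    if df.empty:
        return out
    ds = descriptive_stats(df["duration_ms"])
    out.update(duration_total_ms=ds.total, duration_mean_ms=ds.mean,
               duration_max_ms=ds.maximum, duration_min_ms=ds.minimum)
    da = descriptive_stats(df["amplitude_px"])
    out.update(amplitude_mean_px=da.mean, amplitude_max_px=da.maximum,
               amplitude_min_px=da.minimum)
    dv = descriptive_stats(df["mean_velocity"])
    out.update(velocity_mean_px_s=dv.mean, velocity_max_px_s=dv.maximum,
               velocity_min_px_s=dv.minimum)
    out["peak_velocity_px_s"] = float(df["peak_velocity"].max())
    return out


def pupil_features(sl: Recording, on_roi_only: bool = False) -> dict[str, float]:
    """First/last, extremes, and mean pupil diameter, mm.

    With *on_roi_only* the summary is restricted to samples flagged
    on-ROI; the unrestricted report also carries the on-ROI mean.
    """
    df = sl.pupil
    if on_roi_only:
        if "on_roi" not in df.columns:
            raise ValueError("pupil stream is not ROI-annotated")
        df = df[df["on_roi"]]
    out: dict[str, float] = {"sample_count": int(len(df))}
    nan_keys = ["diameter_first_mm", "diameter_last_mm", "diameter_max_mm",
                "diameter_min_mm", "diameter_mean_mm", "diameter_mean_on_roi_mm"]
    for k in nan_keys:
        out[k] = float("nan")
    if df.empty:
        return out
    d = df["diameter"].to_numpy(dtype=float)
    out.update(diameter_first_mm=float(d[0]), diameter_last_mm=float(d[-1]),
               diameter_max_mm=float(np.nanmax(d)),
               diameter_min_mm=float(np.nanmin(d)),
               diameter_mean_mm=float(np.nanmean(d)))
    if not on_roi_only and "on_roi" in df.columns and df["on_roi"].any():
        out["diameter_mean_on_roi_mm"] = float(
            df.loc[df["on_roi"], "diameter"].mean())
    return out


_EXTRACTORS = {
    "blink": blink_features,
    "fixation": fixation_features,
    "gaze": gaze_features,
    "saccade": saccade_features,
    "pupil": pupil_features,
}

_UNIT_SUFFIXES = (("_ms", "ms"), ("_px_s", "px/s"), ("_px", "px"),
                  ("_rel", "norm"), ("_mm", "mm"))


def _unit_of(index: str) -> str:
    for suffix, unit in _UNIT_SUFFIXES:
        if index.endswith(suffix):
            return unit
    return ""


def extract_report(rec: Recording, epochs: list[Epoch],
                   participant: str = "") -> FeatureReport:
    """Run all five category extractors on every epoch slice.

    The epoch x category grid is always complete: a category that cannot
    be computed contributes empty markers, never aborts the grid.  Each
    epoch also reports its own duration.
    """
    from .events import slice_recording  # local import: avoid cycle

    rows = []
    for k, epoch in enumerate(epochs):
        label = f"{k:03d}:{epoch.name}"
        sl = slice_recording(rec, epoch)
        rows.append((label, "epoch", "duration_ms", epoch.duration_ms, "ms"))
        for cat, extractor in _EXTRACTORS.items():
            try:
                values = extractor(sl)
            except Exception:  # pragma: no cover - defensive; grid must fill
                values = {"count": float("nan")}
            for index, value in values.items():
                rows.append((label, cat, index, value, _unit_of(index)))
    table = pd.DataFrame(rows, columns=["epoch", "category", "index",
                                        "value", "units"])
    return FeatureReport(participant=participant, table=table)


# ------------------------------------------------------------------- filters

def filter_epochs_by_blinks(report: FeatureReport,
                            threshold: int = DEFAULT_BLINK_THRESHOLD
                            ) -> tuple[FeatureReport, list[tuple[str, int]]]:
    """Drop epochs with strictly more than *threshold* blinks.

    Returns the filtered report and the exclusion log of
    ``(epoch, blink count)`` pairs.  The default threshold of 5 encodes
    the acquisition-error rule used in the choice-window study design:
    a typical blink rate of roughly 15–20 per minute makes more than
    five blinks in a few-second window implausible.
    """
    t = report.table
    counts = t[(t["category"] == "blink") & (t["index"] == "count")]
    excluded = [(str(r["epoch"]), int(r["value"]))
                for _, r in counts.iterrows() if r["value"] > threshold]
    bad = {name for name, _ in excluded}
    kept = t[~t["epoch"].isin(bad)].reset_index(drop=True)
    filtered = FeatureReport(participant=report.participant, table=kept,
                             stats=dict(report.stats),
                             exclusions=report.exclusions + excluded)
    return filtered, excluded


# ---------------------------------------------------------------- statistics

@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


def two_sample_ttest(a, b, equal_var: bool = True) -> TTestResult:
    """Independent-samples t-test between two value sequences.

    Student's pooled-variance form by default; ``equal_var=False``
    switches to the Welch unequal-variance form.  Two identical
    zero-variance groups are reported as t = 0, p = 1 rather than NaN.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("groups must contain finite values only")
    if a.var() == 0 and b.var() == 0 and a.mean() == b.mean():
        dof = len(a) + len(b) - 2 if equal_var else float(len(a) + len(b) - 2)
        return TTestResult(t=0.0, df=float(dof), p=1.0)
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    dof = float(res.df) if hasattr(res, "df") else float(len(a) + len(b) - 2)
    return TTestResult(t=float(res.statistic), df=dof, p=float(res.pvalue))
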