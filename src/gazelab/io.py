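"""Reading and writing recording folders in the cloud CSV export dialect.

The export dialect is a folder of comma-separated UTF-8 tables with a
header row.  Canonical file names and columns (the Neon cloud
convention) are listed in :data:`FILE_CANDIDATES` and :data:`ALIASES`;
header matching is tolerant: case-insensitive, surrounding whitespace
ignored, bracketed unit annotations (``[ns]``, ``[px]``, ...) stripped.
Malformed data rows are skipped with a logged warning, never fatal —
validation reports the damage afterwards.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .model import Issue, Recording, empty_stream, ensure_sorted

logger = logging.getLogger(__name__)

#: accepted file names per stream, in preference order
FILE_CANDIDATES: dict[str, tuple[str, ...]] = {
    "gaze": ("gaze.csv",),
    "fixations": ("fixations.csv",),
    "blinks": ("blinks.csv",),
    "saccades": ("saccades.csv",),
    "pupil": ("3d_eye_states.csv", "eye_states.csv", "pupillometry.csv"),
    "events": ("events.csv",),
    "surface_gaze": ("enrichment_gaze.csv", "gaze_on_surface.csv", "surface_gaze.csv"),
    "surface_fixations": (
        "enrichment_fixations.csv",
        "fixations_on_surface.csv",
        "surface_fixations.csv",
    ),
}

_REQUIRED_STREAMS = ("gaze", "fixations", "blinks", "saccades", "pupil", "events")
_ENRICHMENT_STREAMS = ("surface_gaze", "surface_fixations")

#: normalised export header -> canonical column, per stream
ALIASES: dict[str, dict[str, str]] = {
    "gaze": {
        "timestamp": "timestamp",
        "gaze x": "x",
        "gaze y": "y",
        "x": "x",
        "y": "y",
        "worn": "worn",
        "fixation id": "fixation_id",
        "blink id": "blink_id",
    },
    "fixations": {
        "fixation id": "id",
        "id": "id",
        "start timestamp": "start_ts",
        "end timestamp": "end_ts",
        "duration": "duration_ms",
        "fixation x": "cx",
        "fixation y": "cy",
    },
    "blinks": {
        "blink id": "id",
        "id": "id",
        "start timestamp": "start_ts",
        "end timestamp": "end_ts",
        "duration": "duration_ms",
    },
    "saccades": {
        "saccade id": "id",
        "id": "id",
        "start timestamp": "start_ts",
        "end timestamp": "end_ts",
        "duration": "duration_ms",
        "amplitude": "amplitude_px",
        "mean velocity": "mean_velocity",
        "peak velocity": "peak_velocity",
    },
    "pupil": {
        "timestamp": "timestamp",
        "pupil diameter left": "diameter_left",
        "pupil diameter right": "diameter_right",
        "pupil diameter": "diameter",
    },
    "events": {
        "name": "name",
        "timestamp": "timestamp",
        "recording id": "_ignore",
    },
    "surface_gaze": {
        "timestamp": "timestamp",
        "gaze detected on surface": "on_surface",
        "detected on surface": "on_surface",
        "gaze position on surface x": "sx",
        "gaze position on surface y": "sy",
    },
    "surface_fixations": {
        "timestamp": "timestamp",
        "fixation detected on surface": "on_surface",
        "gaze detected on surface": "on_surface",
        "detected on surface": "on_surface",
        "fixation x": "sx",
        "fixation y": "sy",
        "gaze position on surface x": "sx",
        "gaze position on surface y": "sy",
    },
}

_REQUIRED_COLUMNS: dict[str, tuple[str, ...]] = {
    "gaze": ("timestamp", "x", "y"),
    "fixations": ("id", "start_ts", "end_ts"),
    "blinks": ("id", "start_ts", "end_ts"),
    "saccades": ("id", "start_ts", "end_ts"),
    "pupil": ("timestamp",),
    "events": ("name", "timestamp"),
    "surface_gaze": ("timestamp", "on_surface"),
    "surface_fixations": ("timestamp", "on_surface"),
}

_BRACKETS = re.compile(r"\[[^\]]*\]|\([^)]*\)")
_SQUASH = re.compile(r"[\s_]+")

_TRUE = {"true", "1", "1.0", "yes", "t"}
_FALSE = {"false", "0", "0.0", "no", "f", "", "nan", "none"}


class RecordingError(RuntimeError):
    """Fatal problem with a recording folder (missing file, bad table)."""


def normalise_header(header: str) -> str:
    """Canonical form of an export column header."""
    h = _BRACKETS.sub(" ", str(header))
    return _SQUASH.sub(" ", h).strip().lower()


def _parse_bool(series: pd.Series) -> pd.Series:
    s = series.astype(str).str.strip().str.lower()
    out = s.isin(_TRUE)
    bad = ~(s.isin(_TRUE) | s.isin(_FALSE))
    if bad.any():
        logger.warning("unrecognised boolean values coerced to False: %s",
                       sorted(s[bad].unique())[:5])
    return out


def read_stream(path: Path, stream: str) -> pd.DataFrame:
    """Parse one export table into its canonical frame.

    Unknown columns are dropped; unparseable rows are skipped with one
    logged warning giving the count.
    """
    try:
        raw = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise RecordingError(f"{path.name}: cannot be parsed as CSV ({exc})") from exc

    alias = ALIASES[stream]
    rename = {}
    for col in raw.columns:
        key = normalise_header(col)
        if key in alias and alias[key] != "_ignore":
            rename[col] = alias[key]
    raw = raw[list(rename)].rename(columns=rename)
    # first occurrence wins when aliases collide
    raw = raw.loc[:, ~raw.columns.duplicated()]

    required = _REQUIRED_COLUMNS[stream]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise RecordingError(
            f"{path.name}: required column(s) {missing} not found "
            f"(headers matched case/unit-insensitively)"
        )

    out = empty_stream(stream)
    n_in = len(raw)
    if n_in == 0:
        return out

    cols = {}
    bad = pd.Series(False, index=raw.index)
    for c in out.columns:
        if c not in raw.columns:
            fill = False if c in ("worn", "on_surface") else np.nan
            cols[c] = pd.Series([fill] * n_in, index=raw.index)
            continue
        if c in ("worn", "on_surface"):
            cols[c] = _parse_bool(raw[c])
        elif c == "name":
            cols[c] = raw[c].astype(str)
            bad |= cols[c].str.len() == 0
        else:
            num = pd.to_numeric(raw[c], errors="coerce")
            if c in required:
                bad |= num.isna()
            cols[c] = num
    df = pd.DataFrame(cols)
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("%s: skipped %d malformed row(s)", path.name, n_bad)
        df = df[~bad]

    # dtype coercion to the canonical schema
    for c in df.columns:
        target = empty_stream(stream)[c].dtype
        if str(target) == "int64":
            df[c] = df[c].astype("float64").round().astype("int64")
        elif str(target) == "Int64":
            df[c] = df[c].astype("float64").round().astype("Int64")
        elif str(target) == "bool":
            df[c] = df[c].astype(bool)
        elif c != "name":
            df[c] = df[c].astype("float64")

    sort_key = "timestamp" if "timestamp" in df.columns else "start_ts"
    df = ensure_sorted(df, sort_key)

    if stream == "pupil":
        df = _resolve_pupil_diameter(df)
    if stream in ("fixations", "blinks", "saccades") and df["duration_ms"].isna().any():
        dur = (df["end_ts"] - df["start_ts"]) / 1e6
        df["duration_ms"] = df["duration_ms"].fillna(dur)
    return df.reset_index(drop=True)


def _resolve_pupil_diameter(df: pd.DataFrame, how: str = "mean") -> pd.DataFrame:
    """Fill the resolved ``diameter`` column from left/right eyes.

    Both present -> their mean; one present -> that one; an explicitly
    exported combined diameter is kept as-is.
    """
    need = df["diameter"].isna()
    if need.any():
        lr = df[["diameter_left", "diameter_right"]]
        resolved = lr.mean(axis=1, skipna=True) if how == "mean" else lr.min(axis=1)
        df.loc[need, "diameter"] = resolved[need]
    return df


def _find_file(folder: Path, stream: str) -> Path | None:
    lookup = {p.name.lower(): p for p in folder.iterdir() if p.is_file()}
    for cand in FILE_CANDIDATES[stream]:
        if cand in lookup:
            return lookup[cand]
    return None


def load_recording(folder: str | Path, participant: str = "",
                   require_enrichment: bool = True) -> Recording:
    """Load a recording folder into a :class:`Recording`.

    Every core stream table must be present; the enrichment (surface)
    tables are required as well in this version, because ROI gating is
    driven by them.
    """
    folder = Path(folder)
    if not folder.is_dir():
        raise RecordingError(f"recording folder not found: {folder}")

    frames: dict[str, pd.DataFrame] = {}
    for stream in _REQUIRED_STREAMS:
        path = _find_file(folder, stream)
        if path is None:
            raise RecordingError(
                f"required table missing from {folder}: expected one of "
                f"{', '.join(FILE_CANDIDATES[stream])}"
            )
        frames[stream] = read_stream(path, stream)

    for stream in _ENRICHMENT_STREAMS:
        path = _find_file(folder, stream)
        if path is None:
            if require_enrichment:
                raise RecordingError(
                    f"enrichment table missing from {folder} (expected one of "
                    f"{', '.join(FILE_CANDIDATES[stream])}); this version "
                    "requires a surface enrichment for ROI gating"
                )
            frames[stream] = empty_stream(stream)
        else:
            frames[stream] = read_stream(path, stream)

    return Recording(participant=participant, **frames)


def validate_recording(rec: Recording) -> list[Issue]:
    """Pure consistency report over a loaded recording (never raises)."""
    issues: list[Issue] = []

    for name, df in rec.streams():
        if df.empty:
            continue
        key = "timestamp" if "timestamp" in df.columns else "start_ts"
        ts = df[key].to_numpy()
        if name == "events":
            bad = np.flatnonzero(np.diff(ts) < 0)
        else:
            bad = np.flatnonzero(np.diff(ts) <= 0) if key == "timestamp" else \
                np.flatnonzero(np.diff(ts) < 0)
        for i in bad:
            issues.append(Issue(name, "non_monotonic",
                                f"{name}: {key} not increasing at row {i + 1}",
                                (int(i), int(i + 1))))

    blinks = rec.blinks
    for i in range(len(blinks) - 1):
        if int(blinks["end_ts"].iloc[i]) > int(blinks["start_ts"].iloc[i + 1]):
            a, b = int(blinks["id"].iloc[i]), int(blinks["id"].iloc[i + 1])
            issues.append(Issue("blinks", "overlap",
                                f"blinks {a} and {b} overlap in time", (a, b)))

    for name, df in (("fixations", rec.fixations), ("blinks", rec.blinks),
                     ("saccades", rec.saccades)):
        if df.empty:
            continue
        bad = df["end_ts"].to_numpy() <= df["start_ts"].to_numpy()
        for i in np.flatnonzero(bad):
            issues.append(Issue(name, "empty_interval",
                                f"{name[:-1]} {int(df['id'].iloc[i])} has "
                                "end_ts <= start_ts", (int(df["id"].iloc[i]),)))

    if not rec.gaze.empty:
        known = set(rec.fixations["id"].astype(int))
        referenced = set(rec.gaze["fixation_id"].dropna().astype(int))
        for fid in sorted(referenced - known):
            issues.append(Issue("gaze", "dangling_fixation_id",
                                f"gaze references fixation id {fid} absent "
                                "from the fixation table", (fid,)))
        both = rec.gaze["fixation_id"].notna() & rec.gaze["blink_id"].notna()
        for i in np.flatnonzero(both.to_numpy()):
            issues.append(Issue("gaze", "fixation_and_blink",
                                f"gaze row {i} carries both a fixation id and "
                                "a blink id", (int(i),)))
    return issues


def write_outputs(report, figures, out_dir: str | Path, participant: str) -> dict:
    """Write the feature table, the text report, and all figures.

    Filenames are prefixed with the sanitised participant code; ordering
    is deterministic so repeated runs are byte-identical.  Returns a
    manifest mapping artefact kind to written path(s).
    """
    from .features import FeatureReport  # local import: avoid cycle
    from .plots import render_figure

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise RecordingError(f"output directory not writable: {out_dir} ({exc})") from exc

    prefix = sanitise_code(participant)
    assert isinstance(report, FeatureReport)

    table_path = out_dir / f"{prefix}_features.csv"
    table = report.table.sort_values(
        ["epoch", "category", "index"], kind="stable"
    ).reset_index(drop=True)
    table.to_csv(table_path, index=False, lineterminator="\n", float_format="%.9g")

    report_path = out_dir / f"{prefix}_report.txt"
    report_path.write_text(report.to_text(), encoding="utf-8")

    figure_paths = []
    for i, plot in enumerate(figures):
        fig_path = out_dir / f"{prefix}_{i:02d}_{plot.kind}.png"
        render_figure(plot, fig_path)
        figure_paths.append(str(fig_path))

    return {
        "feature_table": str(table_path),
        "text_report": str(report_path),
        "figures": figure_paths,
    }


def sanitise_code(participant: str) -> str:
    """Filesystem-safe filename prefix from a participant code."""
    safe = re.sub(r"[^A-Za-z0-9._-]+", "-", participant.strip())
    return safe or "participant"
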