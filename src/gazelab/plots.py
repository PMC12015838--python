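"""Figure preparation and rendering.

Preparation and rendering are strictly separated: every ``prepare_*``
function returns a :class:`PreparedPlot` whose numeric arrays and
annotations (including colour semantics — green = on-ROI, red =
off-ROI) are plain data and fully testable; :func:`render_figure` then
draws a prepared plot without any numeric transformation beyond axis
mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .model import NS_PER_MS

logger = logging.getLogger(__name__)

PLOT_KINDS = ("pupil_roi_series", "blink_series", "saccade_velocity",
              "saccade_amplitude", "fixation_cloud", "path", "histogram",
              "periodogram", "spectrogram")

KDE_GRID = 256          #: density evaluated on a KDE_GRID x KDE_GRID lattice
DEFAULT_BINS = 30

ON_ROI_COLOR = "green"
OFF_ROI_COLOR = "red"


@dataclass
class PreparedPlot:
    """Numeric content and annotations of one figure, before drawing."""

    kind: str
    series: dict[str, np.ndarray] = field(default_factory=dict)
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in PLOT_KINDS:
            raise ValueError(f"unknown plot kind {self.kind!r}")


def _runs(flags: np.ndarray) -> list[tuple[int, int, bool]]:
    """Maximal constant runs of a boolean array as (start, stop, value)."""
    if flags.size == 0:
        return []
    change = np.flatnonzero(np.diff(flags.astype(int))) + 1
    bounds = np.concatenate([[0], change, [flags.size]])
    return [(int(bounds[i]), int(bounds[i + 1]), bool(flags[bounds[i]]))
            for i in range(len(bounds) - 1)]


def prepare_pupil_roi_series(pupil: pd.DataFrame) -> PreparedPlot:
    """Pupil-diameter time series with on-/off-ROI segments colour-coded.

    Contiguous on-ROI runs are labelled green, off-ROI runs red; blink
    gaps in the eye-state stream show up as drops/breaks in the trace.
    """
    if pupil is None or pupil.empty:
        raise ValueError("pupil stream is empty; nothing to plot")
    if "on_roi" not in pupil.columns:
        raise ValueError("pupil stream is not ROI-annotated")
    ts = pupil["timestamp"].to_numpy(dtype="int64")
    t_s = (ts - ts[0]) / 1e9
    diam = pupil["diameter"].to_numpy(dtype=float)
    flags = pupil["on_roi"].to_numpy(dtype=bool)
    segments = [
        {"start": s, "stop": e,
         "color": ON_ROI_COLOR if v else OFF_ROI_COLOR,
         "label": "on ROI" if v else "off ROI"}
        for s, e, v in _runs(flags)
    ]
    return PreparedPlot(
        kind="pupil_roi_series",
        series={"time_s": t_s, "diameter_mm": diam,
                "on_roi": flags.astype(int)},
        annotations={"segments": segments,
                     "xlabel": "time [s]", "ylabel": "pupil diameter [mm]"},
    )


def prepare_blink_series(blinks: pd.DataFrame,
                         span: tuple[int, int]) -> PreparedPlot:
    """Binary blink step series: 1 inside blink intervals, 0 elsewhere."""
    start, end = span
    edges_t = [start]
    edges_v = [0.0]
    for _, b in blinks.iterrows():
        s, e = int(b["start_ts"]), int(b["end_ts"])
        edges_t += [s, s, e, e]
        edges_v += [0.0, 1.0, 1.0, 0.0]
    edges_t.append(end)
    edges_v.append(0.0)
    t0 = edges_t[0]
    t_s = (np.asarray(edges_t, dtype="int64") - t0) / 1e9
    return PreparedPlot(
        kind="blink_series",
        series={"time_s": t_s, "blink": np.asarray(edges_v)},
        annotations={"n_blinks": int(len(blinks)),
                     "xlabel": "time [s]", "ylabel": "blink (1 = eyes closed)"},
    )


def blink_series_integral_ms(plot: PreparedPlot) -> float:
    """Area under a blink step series, in ms (equals total blink duration)."""
    t = plot.series["time_s"]
    v = plot.series["blink"]
    # rectangle rule on the step representation
    return float(np.sum(np.diff(t) * v[:-1]) * 1e3)


def prepare_saccade_series(saccades: pd.DataFrame,
                           which: str = "velocity") -> PreparedPlot:
    """Per-saccade velocity (mean + peak, px/ms) or amplitude (px) series.

    The x axis is the saccade index in temporal order; velocities are
    converted from px/s to px/ms for display.
    """
    if which not in ("velocity", "amplitude"):
        raise ValueError(f"unknown saccade series {which!r}")
    kind = f"saccade_{which}"
    if saccades is None or saccades.empty:
        logger.warning("no saccades to plot")
        return PreparedPlot(kind=kind,
                            series={"index": np.zeros(0)},
                            annotations={"empty": True})
    index = np.arange(1, len(saccades) + 1, dtype=float)
    if which == "velocity":
        series = {
            "index": index,
            "mean_velocity_px_ms": saccades["mean_velocity"].to_numpy(float) / 1e3,
            "peak_velocity_px_ms": saccades["peak_velocity"].to_numpy(float) / 1e3,
        }
        ylabel = "saccade velocity [px/ms]"
    else:
        series = {"index": index,
                  "amplitude_px": saccades["amplitude_px"].to_numpy(float)}
        ylabel = "saccade amplitude [px]"
    return PreparedPlot(kind=kind, series=series,
                        annotations={"xlabel": "saccade index", "ylabel": ylabel})


def prepare_fixation_cloud(points: np.ndarray, background=None,
                           bandwidth: float | None = None) -> PreparedPlot:
    """Fixation scatter plus a Gaussian kernel density surface.

    The density is evaluated on a :data:`KDE_GRID`-squared lattice
    padded by three kernel bandwidths per axis, so grid quadrature of
    the surface recovers ~all probability mass.  Bandwidth defaults to
    Scott's rule; a scalar override multiplies it.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = len(pts)
    ann: dict = {"xlabel": "x", "ylabel": "y"}
    if background is not None:
        ann["background"] = background
    if n < 2 or np.allclose(pts.var(axis=0), 0):
        logger.warning("fewer than two distinct fixation points; "
                       "scatter only, no density surface")
        return PreparedPlot(kind="fixation_cloud",
                            series={"x": pts[:, 0], "y": pts[:, 1]},
                            annotations=ann | {"density": False})
    kde = gaussian_kde(pts.T, bw_method=bandwidth)
    bw = np.sqrt(np.diag(kde.covariance))
    lo = pts.min(axis=0) - 3 * bw
    hi = pts.max(axis=0) + 3 * bw
    gx = np.linspace(lo[0], hi[0], KDE_GRID)
    gy = np.linspace(lo[1], hi[1], KDE_GRID)
    xx, yy = np.meshgrid(gx, gy)
    density = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    return PreparedPlot(
        kind="fixation_cloud",
        series={"x": pts[:, 0], "y": pts[:, 1],
                "grid_x": gx, "grid_y": gy, "density": density},
        annotations=ann | {"density": True,
                           "cell_area": float((gx[1] - gx[0]) * (gy[1] - gy[0]))},
    )


def prepare_path(points: np.ndarray, mode: str = "absolute") -> PreparedPlot:
    """Ordered gaze/fixation polyline with order markers.

    ``absolute`` expects scene/reference pixels, ``relative`` expects
    surface-normalised coordinates in [0, 1].
    """
    if mode not in ("absolute", "relative"):
        raise ValueError(f"unknown path mode {mode!r}")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("a path needs at least two (x, y) points")
    steps = np.hypot(np.diff(pts[:, 0]), np.diff(pts[:, 1]))
    unit = "norm" if mode == "relative" else "px"
    return PreparedPlot(
        kind="path",
        series={"x": pts[:, 0], "y": pts[:, 1],
                "order": np.arange(len(pts), dtype=float)},
        annotations={"mode": mode, "total_length": float(steps.sum()),
                     "xlabel": f"x [{unit}]", "ylabel": f"y [{unit}]"},
    )


def prepare_histogram(values, bins: int = DEFAULT_BINS) -> PreparedPlot:
    """Counts-per-bin histogram of a value list."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot histogram an empty value list")
    counts, edges = np.histogram(arr, bins=bins)
    return PreparedPlot(
        kind="histogram",
        series={"counts": counts.astype(float), "bin_edges": edges},
        annotations={"n": int(arr.size), "bins": int(bins)},
    )


def prepare_periodogram(freqs: np.ndarray, psd: np.ndarray) -> PreparedPlot:
    return PreparedPlot(kind="periodogram",
                        series={"frequency_hz": np.asarray(freqs, float),
                                "psd": np.asarray(psd, float)},
                        annotations={"xlabel": "frequency [Hz]",
                                     "ylabel": "power spectral density"})


def prepare_spectrogram(freqs, times, sxx) -> PreparedPlot:
    return PreparedPlot(kind="spectrogram",
                        series={"frequency_hz": np.asarray(freqs, float),
                                "time_s": np.asarray(times, float),
                                "power": np.asarray(sxx, float)},
                        annotations={"xlabel": "time [s]",
                                     "ylabel": "frequency [Hz]"})


def render_figure(plot: PreparedPlot, path, size=(8.0, 5.0),
                  dpi: int = 100) -> str:
    """Draw a prepared plot to a raster file (presentation only)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=size)
    s, ann = plot.series, plot.annotations
    try:
        if ann.get("empty"):
            ax.text(0.5, 0.5, "no data", ha="center", va="center",
                    transform=ax.transAxes)
        elif plot.kind == "pupil_roi_series":
            t, d = s["time_s"], s["diameter_mm"]
            for seg in ann["segments"]:
                sl = slice(seg["start"], min(seg["stop"] + 1, len(t)))
                ax.plot(t[sl], d[sl], color=seg["color"], lw=0.8)
        elif plot.kind == "blink_series":
            ax.plot(s["time_s"], s["blink"], color="black", lw=0.8)
            ax.set_ylim(-0.1, 1.2)
        elif plot.kind == "saccade_velocity":
            ax.plot(s["index"], s["mean_velocity_px_ms"], color="tab:blue",
                    label="mean")
            ax.plot(s["index"], s["peak_velocity_px_ms"], color="tab:orange",
                    label="peak")
            ax.legend()
        elif plot.kind == "saccade_amplitude":
            ax.plot(s["index"], s["amplitude_px"], color="tab:blue")
        elif plot.kind == "fixation_cloud":
            if ann.get("background") is not None:
                ax.imshow(ann["background"], origin="upper", alpha=0.7)
            if ann.get("density"):
                ax.contourf(s["grid_x"], s["grid_y"], s["density"],
                            levels=12, cmap="viridis", alpha=0.6)
            ax.scatter(s["x"], s["y"], s=8, color="crimson")
        elif plot.kind == "path":
            ax.plot(s["x"], s["y"], "-o", ms=3, lw=0.8)
            for i in (0, len(s["x"]) - 1):
                ax.annotate(str(int(s["order"][i])), (s["x"][i], s["y"][i]))
        elif plot.kind == "histogram":
            edges = s["bin_edges"]
            ax.bar(edges[:-1], s["counts"], width=np.diff(edges),
                   align="edge", edgecolor="white")
        elif plot.kind == "periodogram":
            ax.semilogy(s["frequency_hz"], np.maximum(s["psd"], 1e-30))
        elif plot.kind == "spectrogram":
            ax.pcolormesh(s["time_s"], s["frequency_hz"], s["power"],
                          shading="auto")
        ax.set_xlabel(ann.get("xlabel", ""))
        ax.set_ylabel(ann.get("ylabel", ""))
        fig.tight_layout()
        fig.savefig(path, dpi=dpi)
    finally:
        plt.close(fig)
    return str(path)
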