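"""Frequency-domain analysis of the pupillometry series.

Pupil samples arrive irregularly (and with gaps where blinks suppressed
the eye-state estimate), so spectra are computed in three steps: linear
interpolation onto a uniform grid at a chosen rate, then an averaged
modified periodogram (Welch) or a short-time spectrogram over tapered,
overlapping segments.  Gaps longer than one second are interpolated
through like any other interval but flagged in the returned metadata,
so the caller can judge how much of the spectrum rests on interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as ssig

DEFAULT_RATE_HZ = 200.0       #: nominal eye-state sampling rate
DEFAULT_SEGMENT = 256         #: Welch segment length, samples
DEFAULT_OVERLAP = 0.5         #: fractional segment overlap
DEFAULT_WINDOW = "hann"
GAP_FLAG_S = 1.0              #: gaps longer than this are flagged


@dataclass
class UniformSeries:
    """A uniformly resampled series with provenance metadata."""

    times_s: np.ndarray          # seconds from series start
    values: np.ndarray
    rate_hz: float
    gaps: list[tuple[float, float]] = field(default_factory=list)
    gap_fraction: float = 0.0    # fraction of grid points inside flagged gaps

    def __len__(self) -> int:
        return len(self.values)


def resample_uniform(timestamps_ns, values, rate_hz: float = DEFAULT_RATE_HZ
                     ) -> UniformSeries:
    """Linearly interpolate an irregular series onto a uniform grid.

    The grid spans the input exactly (first to last sample).  Input
    gaps longer than :data:`GAP_FLAG_S` are filled by the interpolation
    but recorded in ``gaps`` (as start/end seconds from series start).
    """
    ts = np.asarray(timestamps_ns, dtype="int64")
    vals = np.asarray(values, dtype=float)
    if ts.size != vals.size:
        raise ValueError("timestamps and values differ in length")
    if ts.size < 2:
        raise ValueError("resampling needs at least two samples")
    if rate_hz <= 0:
        raise ValueError("rate must be positive")
    t_s = (ts - ts[0]) / 1e9
    # tolerance keeps grid points that land exactly on the last sample
    n = int(np.floor(t_s[-1] * rate_hz + 1e-9)) + 1
    grid = np.arange(n) / rate_hz
    out = np.interp(grid, t_s, vals)

    gaps: list[tuple[float, float]] = []
    dt = np.diff(t_s)
    for i in np.flatnonzero(dt > GAP_FLAG_S):
        gaps.append((float(t_s[i]), float(t_s[i + 1])))
    in_gap = np.zeros(n, dtype=bool)
    for lo, hi in gaps:
        in_gap |= (grid > lo) & (grid < hi)
    return UniformSeries(times_s=grid, values=out, rate_hz=rate_hz,
                         gaps=gaps, gap_fraction=float(in_gap.mean()))


def _check_segment(series: UniformSeries, segment_length: int) -> None:
    if len(series) < segment_length:
        raise ValueError(
            f"series of {len(series)} samples is shorter than one segment "
            f"({segment_length}); lower segment_length or record longer "
            f"(>= {segment_length / series.rate_hz:.1f} s at "
            f"{series.rate_hz:g} Hz)"
        )


def welch_periodogram(series: UniformSeries,
                      segment_length: int = DEFAULT_SEGMENT,
                      overlap: float = DEFAULT_OVERLAP,
                      window: str = DEFAULT_WINDOW
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Averaged modified periodogram (power spectral density).

    Returns (frequencies Hz, PSD) over 0..rate/2.  Segments are
    mean-detrended and tapered before averaging.
    """
    _check_segment(series, segment_length)
    freqs, psd = ssig.welch(
        series.values, fs=series.rate_hz, window=window,
        nperseg=segment_length, noverlap=int(overlap * segment_length),
        detrend="constant",
    )
    return freqs, psd


def spectrogram(series: UniformSeries,
                segment_length: int = DEFAULT_SEGMENT,
                overlap: float = DEFAULT_OVERLAP,
                window: str = DEFAULT_WINDOW
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time power spectra on a sliding window.

    Returns (frequencies Hz, segment times s from series start, PSD
    matrix of shape ``(n_freqs, n_times)``).
    """
    _check_segment(series, segment_length)
    freqs, times, sxx = ssig.spectrogram(
        series.values, fs=series.rate_hz, window=window,
        nperseg=segment_length, noverlap=int(overlap * segment_length),
        detrend="constant",
    )
    return freqs, times, sxx


def dominant_frequency(freqs: np.ndarray, psd: np.ndarray) -> float:
    """Frequency of the global spectral peak (Hz)."""
    return float(freqs[int(np.argmax(psd))])
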