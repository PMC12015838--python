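"""Synthetic recording generator with exact ground truth.

Generates recording folders in the cloud export dialect whose planted
inventory — every blink, fixation, saccade, gaze sample, pupil sample,
and event, plus per-stream ROI fractions — is known exactly and written
to a manifest.  Two entry points:

* :func:`generate_recording` — a stochastic session: alternating
  fixations and inter-fixation movements, a Poisson blink process, a
  slowly drifting noisy pupil (optionally with a planted oscillation),
  and a configurable ROI on/off schedule.  Gaze and pupil samples are
  omitted during blinks, mirroring device dropouts.
* :func:`scripted_recording` — a deterministic, noise-free session
  built from explicit interval lists, for exact-equality tests.

The statistical anchors of the default configuration are the study
conditions this pipeline was designed around: ~200 Hz sampling, a
typical blink rate in the 15–20 per minute range (default 17.5), and
fixation durations of a few hundred milliseconds.  The MDMT preset
(:func:`mdmt_events`) encodes the packaged worked example: 56 audio
dilemmas of 27.8 ± 3.00 s, choice windows of 4.34 ± 2.01 s truncated
at 0.5 s, 1 s inter-stimulus intervals, and a 30 s pause after every
7th dilemma.

These fixtures are statistical scaffolding, not oculomotor simulation:
the amplitude–velocity link is a simple monotone factor, not a main
sequence.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import NS_PER_S, Recording, empty_stream

# ------------------------------------------------------------- MDMT preset

MDMT_N_DILEMMAS = 56
MDMT_ISI_S = 1.0
MDMT_AUDIO_MEAN_S = 27.8
MDMT_AUDIO_SD_S = 3.00
MDMT_CHOICE_MEAN_S = 4.34
MDMT_CHOICE_SD_S = 2.01
MDMT_CHOICE_MIN_S = 0.5
MDMT_PAUSE_EVERY = 7
MDMT_PAUSE_S = 30.0
#: the task design: one non-moral block plus six condition x variation
#: blocks (personal/impersonal x unobserved/media/authority), 8 dilemmas each
MDMT_BLOCKS = (
    ("NM", None, 8),
    ("MP", "U", 8), ("MP", "A", 8), ("MP", "M", 8),
    ("MI", "U", 8), ("MI", "A", 8), ("MI", "M", 8),
)


def mdmt_choice_truncated_mean(mean_s: float = MDMT_CHOICE_MEAN_S,
                               sd_s: float = MDMT_CHOICE_SD_S,
                               min_s: float = MDMT_CHOICE_MIN_S) -> float:
    """Analytic mean of the choice-window model (normal truncated below)."""
    a = (min_s - mean_s) / sd_s
    return float(sps.truncnorm.mean(a, np.inf, loc=mean_s, scale=sd_s))


def mdmt_events(n_dilemmas: int = MDMT_N_DILEMMAS, seed: int = 0,
                start_ts: int = 0) -> tuple[pd.DataFrame, dict]:
    """Event stream of an MDMT session, with the planted timing inventory.

    Per dilemma: 1 s ISI, the audio stimulus (normal, 27.8 ± 3.00 s),
    another 1 s ISI, then the choice window (normal, 4.34 ± 2.01 s,
    truncated below at 0.5 s).  A 30 s pause follows every 7th dilemma.
    Returns the event table (ns timestamps) and an info dict holding the
    drawn per-dilemma durations and the planted means.
    """
    if n_dilemmas < 1:
        raise ValueError("need at least one dilemma")
    rng = np.random.default_rng(seed)
    audio = rng.normal(MDMT_AUDIO_MEAN_S, MDMT_AUDIO_SD_S, n_dilemmas)
    audio = np.maximum(audio, 1.0)  # an audio file cannot have <= 0 length
    a = (MDMT_CHOICE_MIN_S - MDMT_CHOICE_MEAN_S) / MDMT_CHOICE_SD_S
    choice = sps.truncnorm.rvs(a, np.inf, loc=MDMT_CHOICE_MEAN_S,
                               scale=MDMT_CHOICE_SD_S, size=n_dilemmas,
                               random_state=rng)
    rows: list[tuple[str, int]] = []
    t = float(start_ts) / NS_PER_S
    for i in range(n_dilemmas):
        rows.append(("isi", t)); t += MDMT_ISI_S
        rows.append((f"audio_{i + 1:03d}", t)); t += float(audio[i])
        rows.append(("isi", t)); t += MDMT_ISI_S
        rows.append((f"choice_{i + 1:03d}", t)); t += float(choice[i])
        if (i + 1) % MDMT_PAUSE_EVERY == 0 and (i + 1) < n_dilemmas:
            rows.append(("pause", t)); t += MDMT_PAUSE_S
    rows.append(("end", t))
    events = pd.DataFrame({
        "name": [r[0] for r in rows],
        "timestamp": np.asarray([round(r[1] * NS_PER_S) for r in rows],
                                dtype="int64"),
    })
    info = {
        "n_dilemmas": n_dilemmas,
        "audio_durations_s": audio.tolist(),
        "choice_durations_s": choice.tolist(),
        "planted_audio_mean_s": MDMT_AUDIO_MEAN_S,
        "planted_audio_sd_s": MDMT_AUDIO_SD_S,
        "planted_choice_mean_s": mdmt_choice_truncated_mean(),
        "planted_choice_sd_s": MDMT_CHOICE_SD_S,
        "total_duration_s": t - float(start_ts) / NS_PER_S,
    }
    return events, info


# ------------------------------------------------------------ configuration

@dataclass
class SimulationConfig:
    """Knobs of the stochastic recording generator.

    Defaults describe a plausible screen-watching session at the
    device's nominal 200 Hz: fixations of ~250 ms (lognormal), 50 ms
    inter-fixation movements, 17.5 blinks per minute of ~150 ms, and a
    3.5 mm pupil with slow drift and mild measurement noise.
    """

    duration_s: float = 60.0
    gaze_rate_hz: float = 200.0
    scene_width_px: float = 1600.0
    scene_height_px: float = 1200.0
    fixation_duration_mean_ms: float = 250.0
    fixation_duration_sd_ms: float = 100.0
    movement_duration_mean_ms: float = 50.0
    movement_duration_sd_ms: float = 15.0
    gaze_jitter_px: float = 2.0
    blink_rate_per_min: float = 17.5
    blink_duration_mean_ms: float = 150.0
    blink_duration_sd_ms: float = 40.0
    pupil_baseline_mm: float = 3.5
    pupil_drift_mm: float = 0.2
    pupil_noise_sd_mm: float = 0.05
    anisocoria_sd_mm: float = 0.05
    pupil_osc_hz: float | None = None
    pupil_osc_amp_mm: float = 0.0
    #: list of (start_s, end_s, on) tiles; None = on-ROI throughout;
    #: uncovered time is off-ROI
    roi_schedule: list[tuple[float, float, bool]] | None = None
    #: list of (name, t_s); None = a single start/end pair
    events: list[tuple[str, float]] | None = None
    seed: int = 0

    def validate(self) -> None:
        positive = ["duration_s", "gaze_rate_hz", "fixation_duration_mean_ms",
                    "fixation_duration_sd_ms", "movement_duration_mean_ms",
                    "blink_rate_per_min", "blink_duration_mean_ms",
                    "pupil_baseline_mm"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"SimulationConfig.{name} must be positive")
        if self.roi_schedule is not None:
            for lo, hi, _ in self.roi_schedule:
                if not (0 <= lo < hi <= self.duration_s):
                    raise ValueError(
                        f"roi_schedule tile ({lo}, {hi}) outside the "
                        f"recording duration {self.duration_s}")
        if self.events is not None:
            for _, t in self.events:
                if not (0 <= t <= self.duration_s):
                    raise ValueError(f"event at {t} s outside the recording")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and sd."""
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _place_gaze(emitted: np.ndarray, fix_starts, fix_ends, fix_ids,
                fix_cx, fix_cy, default_xy: tuple[float, float]
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free gaze position and fixation label per emitted sample.

    Samples inside fixation *j* sit at its centroid and carry its id;
    samples between fixations interpolate linearly between the two
    centroids; samples before the first / after the last fixation hold
    its centroid.
    """
    n = len(emitted)
    n_fix = len(fix_starts)
    x = np.full(n, default_xy[0], float)
    y = np.full(n, default_xy[1], float)
    fixation_id = np.full(n, np.nan)
    if n_fix == 0 or n == 0:
        return x, y, fixation_id
    j = np.searchsorted(fix_ends, emitted, side="right")
    jc = np.clip(j, 0, n_fix - 1)
    in_fix = (j < n_fix) & (emitted >= fix_starts[jc])
    x[in_fix] = fix_cx[j[in_fix]]
    y[in_fix] = fix_cy[j[in_fix]]
    fixation_id[in_fix] = fix_ids[j[in_fix]]
    between = (~in_fix) & (j > 0) & (j < n_fix)
    if between.any():
        a = j[between] - 1
        b = j[between]
        gap = np.maximum(fix_starts[b] - fix_ends[a], 1)
        frac = (emitted[between] - fix_ends[a]) / gap
        x[between] = fix_cx[a] + frac * (fix_cx[b] - fix_cx[a])
        y[between] = fix_cy[a] + frac * (fix_cy[b] - fix_cy[a])
    before = (~in_fix) & (j == 0)
    x[before], y[before] = fix_cx[0], fix_cy[0]
    after = j >= n_fix
    x[after], y[after] = fix_cx[-1], fix_cy[-1]
    return x, y, fixation_id


def _schedule_flags(times_ns: np.ndarray, schedule, duration_s: float
                    ) -> np.ndarray:
    if schedule is None:
        schedule = [(0.0, duration_s, True)]
    flags = np.zeros(len(times_ns), dtype=bool)
    t_s = times_ns / NS_PER_S
    for lo, hi, on in schedule:
        if on:
            flags |= (t_s >= lo) & (t_s < hi)
    return flags


# ---------------------------------------------------------------- generator

def generate_recording(config: SimulationConfig,
                       participant: str = "sim") -> tuple[Recording, dict]:
    """Simulate one session; returns the recording and its manifest.

    Fully reproducible from ``config.seed``.  Use
    :func:`write_recording_folder` to materialise it as an export
    folder.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    dur_ns = round(config.duration_s * NS_PER_S)

    # --- fixation / movement alternation -------------------------------
    fmu, fsig = _lognormal_params(config.fixation_duration_mean_ms,
                                  config.fixation_duration_sd_ms)
    fix_rows = []
    t = 0
    fid = 1
    cx = rng.uniform(0.1, 0.9) * config.scene_width_px
    cy = rng.uniform(0.1, 0.9) * config.scene_height_px
    centroids = {}
    while True:
        f_ms = float(rng.lognormal(fmu, fsig))
        end = t + round(f_ms * 1e6)
        if end >= dur_ns:
            break
        fix_rows.append({"id": fid, "start_ts": t, "end_ts": end,
                         "duration_ms": (end - t) / 1e6, "cx": cx, "cy": cy})
        centroids[fid] = (cx, cy)
        m_ms = max(10.0, float(rng.normal(config.movement_duration_mean_ms,
                                          config.movement_duration_sd_ms)))
        t = end + round(m_ms * 1e6)
        fid += 1
        cx = rng.uniform(0.05, 0.95) * config.scene_width_px
        cy = rng.uniform(0.05, 0.95) * config.scene_height_px
    fixations = pd.DataFrame(fix_rows) if fix_rows else empty_stream("fixations")
    if fix_rows:
        fixations = fixations.astype({"id": "Int64", "start_ts": "int64",
                                      "end_ts": "int64"})

    # --- blinks: Poisson count, uniform placement, non-overlapping ------
    bmu, bsig = _lognormal_params(config.blink_duration_mean_ms,
                                  config.blink_duration_sd_ms)
    lam = config.blink_rate_per_min * config.duration_s / 60.0
    n_blinks = int(rng.poisson(lam))
    blink_rows = []
    if n_blinks:
        durs_ns = np.round(rng.lognormal(bmu, bsig, n_blinks) * 1e6).astype("int64")
        for _ in range(200):
            starts = np.sort(rng.uniform(0, dur_ns - durs_ns.max(), n_blinks))
            starts = np.round(starts).astype("int64")
            ends = starts + durs_ns
            if np.all(starts[1:] > ends[:-1]):
                break
        else:  # pragma: no cover - only at implausible blink rates
            keep = np.ones(n_blinks, dtype=bool)
            for i in range(1, n_blinks):
                if starts[i] <= ends[i - 1]:
                    keep[i] = False
            starts, ends = starts[keep], ends[keep]
        blink_rows = [{"id": i + 1, "start_ts": int(s), "end_ts": int(e),
                       "duration_ms": (int(e) - int(s)) / 1e6}
                      for i, (s, e) in enumerate(zip(starts, ends))]
    blinks = pd.DataFrame(blink_rows) if blink_rows else empty_stream("blinks")
    if blink_rows:
        blinks = blinks.astype({"id": "Int64", "start_ts": "int64",
                                "end_ts": "int64"})

    # --- saccades = the inter-fixation transitions ----------------------
    sac_rows = []
    for i in range(len(fix_rows) - 1):
        a, b = fix_rows[i], fix_rows[i + 1]
        amp = float(np.hypot(b["cx"] - a["cx"], b["cy"] - a["cy"]))
        s, e = a["end_ts"], b["start_ts"]
        dur_s = (e - s) / NS_PER_S
        mean_v = max(amp / dur_s, 1e-9)
        sac_rows.append({"id": i + 1, "start_ts": s, "end_ts": e,
                         "duration_ms": (e - s) / 1e6, "amplitude_px": amp,
                         "mean_velocity": mean_v, "peak_velocity": 1.8 * mean_v})
    saccades = pd.DataFrame(sac_rows) if sac_rows else empty_stream("saccades")
    if sac_rows:
        saccades = saccades.astype({"id": "Int64", "start_ts": "int64",
                                    "end_ts": "int64"})

    # --- gaze samples ----------------------------------------------------
    period_ns = round(NS_PER_S / config.gaze_rate_hz)
    times = np.arange(0, dur_ns, period_ns, dtype="int64")
    in_blink = np.zeros(len(times), dtype=bool)
    for b in blink_rows:
        in_blink |= (times >= b["start_ts"]) & (times < b["end_ts"])
    emitted = times[~in_blink]

    if len(fixations):
        fix_starts = fixations["start_ts"].to_numpy("int64")
        fix_ends = fixations["end_ts"].to_numpy("int64")
        fix_ids = fixations["id"].to_numpy("int64")
        fix_cx = fixations["cx"].to_numpy(float)
        fix_cy = fixations["cy"].to_numpy(float)
    else:
        fix_starts = fix_ends = fix_ids = np.array([], "int64")
        fix_cx = fix_cy = np.array([], float)
    x, y, fixation_id = _place_gaze(
        emitted, fix_starts, fix_ends, fix_ids, fix_cx, fix_cy,
        default_xy=(config.scene_width_px / 2, config.scene_height_px / 2))
    x = x + rng.normal(0.0, config.gaze_jitter_px, len(emitted))
    y = y + rng.normal(0.0, config.gaze_jitter_px, len(emitted))
    gaze = pd.DataFrame({
        "timestamp": emitted, "x": x, "y": y, "worn": True,
        "fixation_id": pd.array(fixation_id, dtype="float64"),
        "blink_id": pd.Series([pd.NA] * len(emitted), dtype="Int64"),
    })
    gaze["fixation_id"] = gaze["fixation_id"].round().astype("Int64")

    # movements that actually carry emitted samples (the true inventory)
    between = gaze["fixation_id"].isna().to_numpy()
    prev_fix = gaze["fixation_id"].ffill()
    next_fix = gaze["fixation_id"].bfill()
    realised = prev_fix[between & prev_fix.notna().to_numpy()
                        & next_fix.notna().to_numpy()]
    n_movements = int(realised.nunique())

    # --- pupil (eye-state) samples: same grid, same blink dropouts ------
    t_s = emitted / NS_PER_S
    diameter = (config.pupil_baseline_mm
                + config.pupil_drift_mm
                * np.sin(2 * np.pi * t_s / max(config.duration_s, 1.0)))
    if config.pupil_osc_hz:
        diameter = diameter + config.pupil_osc_amp_mm * np.sin(
            2 * np.pi * config.pupil_osc_hz * t_s)
    diameter = diameter + rng.normal(0.0, config.pupil_noise_sd_mm, len(emitted))
    aniso = rng.normal(0.0, config.anisocoria_sd_mm, len(emitted))
    pupil = pd.DataFrame({
        "timestamp": emitted,
        "diameter_left": diameter + aniso,
        "diameter_right": diameter - aniso,
        "diameter": diameter,
    })

    # --- enrichment (surface) streams -----------------------------------
    on_flags = _schedule_flags(emitted, config.roi_schedule, config.duration_s)
    sx = np.clip(gaze["x"].to_numpy() / config.scene_width_px, 0, 1)
    sy = np.clip(gaze["y"].to_numpy() / config.scene_height_px, 0, 1)
    surface_gaze = pd.DataFrame({
        "timestamp": emitted, "on_surface": on_flags,
        "sx": np.where(on_flags, sx, np.nan),
        "sy": np.where(on_flags, sy, np.nan),
    })
    if len(fixations):
        mids = ((fixations["start_ts"] + fixations["end_ts"]) // 2).to_numpy("int64")
        f_on = _schedule_flags(mids, config.roi_schedule, config.duration_s)
        surface_fixations = pd.DataFrame({
            "timestamp": fixations["start_ts"].to_numpy("int64"),
            "on_surface": f_on,
            "sx": np.where(f_on, np.clip(fixations["cx"] / config.scene_width_px, 0, 1), np.nan),
            "sy": np.where(f_on, np.clip(fixations["cy"] / config.scene_height_px, 0, 1), np.nan),
        })
    else:
        surface_fixations = empty_stream("surface_fixations")

    # --- events ----------------------------------------------------------
    ev = config.events if config.events is not None else \
        [("start", 0.0), ("end", config.duration_s)]
    events = pd.DataFrame({
        "name": [e[0] for e in ev],
        "timestamp": np.asarray([round(e[1] * NS_PER_S) for e in ev], "int64"),
    }).sort_values("timestamp", kind="stable").reset_index(drop=True)

    rec = Recording(gaze=gaze, fixations=fixations, blinks=blinks,
                    saccades=saccades, pupil=pupil, events=events,
                    surface_gaze=surface_gaze,
                    surface_fixations=surface_fixations,
                    participant=participant)

    manifest = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "counts": {
            "fixations": int(len(fixations)),
            "blinks": int(len(blinks)),
            "saccades": int(len(saccades)),
            "movements": n_movements,
            "gaze_samples": int(len(gaze)),
            "pupil_samples": int(len(pupil)),
            "events": int(len(events)),
        },
        "blink_total_duration_ms": float(blinks["duration_ms"].sum()) if len(blinks) else 0.0,
        "fixation_duration_mean_ms": float(fixations["duration_ms"].mean()) if len(fixations) else None,
        "roi": {
            "gaze_on_fraction": float(on_flags.mean()) if len(on_flags) else None,
            "fixation_on_fraction": float(surface_fixations["on_surface"].mean()) if len(surface_fixations) else None,
        },
        "events": [{"name": n, "t_s": float(t)} for n, t in ev],
    }
    _check_manifest(rec, manifest)
    return rec, manifest


def _check_manifest(rec: Recording, manifest: dict) -> None:
    """Generation-time consistency check: manifest <-> streams."""
    c = manifest["counts"]
    pairs = [("fixations", rec.fixations), ("blinks", rec.blinks),
             ("saccades", rec.saccades), ("gaze_samples", rec.gaze),
             ("pupil_samples", rec.pupil), ("events", rec.events)]
    for key, df in pairs:
        if c[key] != len(df):
            raise AssertionError(
                f"manifest inconsistency: {key} count {c[key]} != {len(df)}")


# ----------------------------------------------------------- scripted mode

def scripted_recording(script: dict, participant: str = "scripted"
                       ) -> tuple[Recording, dict]:
    """Deterministic, noise-free recording from explicit interval lists.

    ``script`` keys (all optional unless noted):

    * ``duration_s`` (required), ``gaze_rate_hz`` (default 200)
    * ``fixations``: list of ``(id, start_ts, end_ts, cx, cy)`` in ns/px
    * ``blinks``: list of ``(id, start_ts, end_ts)``
    * ``saccades``: list of ``(id, start_ts, end_ts, amplitude,
      mean_velocity, peak_velocity)``; derived from consecutive
      fixations when omitted
    * ``pupil_baseline_mm`` (default 3.0)
    * ``roi_schedule``: list of ``(start_s, end_s, on)``; default all-on
    * ``events``: list of ``(name, t_s)``; default start/end

    Internal inconsistencies (unordered or overlapping intervals) are
    fatal, naming the clash.
    """
    if "duration_s" not in script:
        raise ValueError("script needs a duration_s")
    cfg = SimulationConfig(
        duration_s=float(script["duration_s"]),
        gaze_rate_hz=float(script.get("gaze_rate_hz", 200.0)),
        gaze_jitter_px=0.0, pupil_noise_sd_mm=1e-12, anisocoria_sd_mm=0.0,
        pupil_drift_mm=0.0,
        pupil_baseline_mm=float(script.get("pupil_baseline_mm", 3.0)),
        roi_schedule=script.get("roi_schedule"),
        events=script.get("events"),
        seed=0,
    )
    cfg.validate()
    dur_ns = round(cfg.duration_s * NS_PER_S)

    fix_spec = sorted(script.get("fixations", []), key=lambda r: r[1])
    for i in range(1, len(fix_spec)):
        if fix_spec[i][1] < fix_spec[i - 1][2]:
            raise ValueError(f"fixations {fix_spec[i - 1][0]} and "
                             f"{fix_spec[i][0]} overlap")
    blink_spec = sorted(script.get("blinks", []), key=lambda r: r[1])
    for i in range(1, len(blink_spec)):
        if blink_spec[i][1] < blink_spec[i - 1][2]:
            raise ValueError(f"blinks {blink_spec[i - 1][0]} and "
                             f"{blink_spec[i][0]} overlap")
    for name, rows in (("fixation", fix_spec), ("blink", blink_spec)):
        for r in rows:
            if r[2] <= r[1]:
                raise ValueError(f"{name} {r[0]} has end <= start")
            if r[1] < 0 or r[2] > dur_ns:
                raise ValueError(f"{name} {r[0]} lies outside the recording")

    fixations = pd.DataFrame(
        [{"id": r[0], "start_ts": int(r[1]), "end_ts": int(r[2]),
          "duration_ms": (int(r[2]) - int(r[1])) / 1e6,
          "cx": float(r[3]), "cy": float(r[4])} for r in fix_spec]
    ) if fix_spec else empty_stream("fixations")
    blinks = pd.DataFrame(
        [{"id": r[0], "start_ts": int(r[1]), "end_ts": int(r[2]),
          "duration_ms": (int(r[2]) - int(r[1])) / 1e6} for r in blink_spec]
    ) if blink_spec else empty_stream("blinks")

    if "saccades" in script:
        saccades = pd.DataFrame(
            [{"id": r[0], "start_ts": int(r[1]), "end_ts": int(r[2]),
              "duration_ms": (int(r[2]) - int(r[1])) / 1e6,
              "amplitude_px": float(r[3]), "mean_velocity": float(r[4]),
              "peak_velocity": float(r[5])} for r in script["saccades"]]
        ) if script["saccades"] else empty_stream("saccades")
    else:
        sac_rows = []
        for i in range(len(fix_spec) - 1):
            a, b = fix_spec[i], fix_spec[i + 1]
            if b[1] <= a[2]:
                continue
            amp = float(np.hypot(b[3] - a[3], b[4] - a[4]))
            mv = max(amp / ((b[1] - a[2]) / NS_PER_S), 1e-9)
            sac_rows.append({"id": i + 1, "start_ts": int(a[2]),
                             "end_ts": int(b[1]),
                             "duration_ms": (b[1] - a[2]) / 1e6,
                             "amplitude_px": amp, "mean_velocity": mv,
                             "peak_velocity": 1.8 * mv})
        saccades = pd.DataFrame(sac_rows) if sac_rows else empty_stream("saccades")

    # gaze / pupil / surface grids: reuse the generator mechanics with a
    # zero-noise configuration and the explicit inventories
    period_ns = round(NS_PER_S / cfg.gaze_rate_hz)
    times = np.arange(0, dur_ns, period_ns, dtype="int64")
    in_blink = np.zeros(len(times), dtype=bool)
    for r in blink_spec:
        in_blink |= (times >= r[1]) & (times < r[2])
    emitted = times[~in_blink]

    x, y, fixation_id = _place_gaze(
        emitted,
        np.asarray([r[1] for r in fix_spec], "int64"),
        np.asarray([r[2] for r in fix_spec], "int64"),
        np.asarray([r[0] for r in fix_spec], "int64"),
        np.asarray([r[3] for r in fix_spec], float),
        np.asarray([r[4] for r in fix_spec], float),
        default_xy=(0.5 * cfg.scene_width_px, 0.5 * cfg.scene_height_px))
    gaze = pd.DataFrame({
        "timestamp": emitted, "x": x, "y": y, "worn": True,
        "fixation_id": pd.array(fixation_id, dtype="float64"),
        "blink_id": pd.Series([pd.NA] * len(emitted), dtype="Int64"),
    })
    gaze["fixation_id"] = gaze["fixation_id"].round().astype("Int64")

    pupil = pd.DataFrame({
        "timestamp": emitted,
        "diameter_left": np.full(len(emitted), cfg.pupil_baseline_mm),
        "diameter_right": np.full(len(emitted), cfg.pupil_baseline_mm),
        "diameter": np.full(len(emitted), cfg.pupil_baseline_mm),
    })

    on_flags = _schedule_flags(emitted, cfg.roi_schedule, cfg.duration_s)
    surface_gaze = pd.DataFrame({
        "timestamp": emitted, "on_surface": on_flags,
        "sx": np.where(on_flags, np.clip(x / cfg.scene_width_px, 0, 1), np.nan),
        "sy": np.where(on_flags, np.clip(y / cfg.scene_height_px, 0, 1), np.nan),
    })
    if len(fixations):
        mids = ((fixations["start_ts"] + fixations["end_ts"]) // 2).to_numpy("int64")
        f_on = _schedule_flags(mids, cfg.roi_schedule, cfg.duration_s)
        surface_fixations = pd.DataFrame({
            "timestamp": fixations["start_ts"].to_numpy("int64"),
            "on_surface": f_on,
            "sx": np.where(f_on, np.clip(fixations["cx"] / cfg.scene_width_px, 0, 1), np.nan),
            "sy": np.where(f_on, np.clip(fixations["cy"] / cfg.scene_height_px, 0, 1), np.nan),
        })
    else:
        surface_fixations = empty_stream("surface_fixations")

    ev = cfg.events if cfg.events is not None else \
        [("start", 0.0), ("end", cfg.duration_s)]
    events = pd.DataFrame({
        "name": [e[0] for e in ev],
        "timestamp": np.asarray([round(e[1] * NS_PER_S) for e in ev], "int64"),
    }).sort_values("timestamp", kind="stable").reset_index(drop=True)

    rec = Recording(gaze=gaze, fixations=fixations.reset_index(drop=True),
                    blinks=blinks.reset_index(drop=True),
                    saccades=saccades.reset_index(drop=True),
                    pupil=pupil, events=events, surface_gaze=surface_gaze,
                    surface_fixations=surface_fixations,
                    participant=participant)
    manifest = {
        "script": True,
        "counts": {
            "fixations": int(len(fixations)),
            "blinks": int(len(blinks)),
            "saccades": int(len(saccades)),
            "gaze_samples": int(len(gaze)),
            "pupil_samples": int(len(pupil)),
            "events": int(len(events)),
        },
        "blink_total_duration_ms": float(blinks["duration_ms"].sum()) if len(blinks) else 0.0,
        "fixation_durations_ms": fixations["duration_ms"].tolist() if len(fixations) else [],
        "roi": {"gaze_on_fraction": float(on_flags.mean()) if len(on_flags) else None},
        "events": [{"name": n, "t_s": float(t)} for n, t in ev],
    }
    _check_manifest(rec, manifest)
    return rec, manifest


# ------------------------------------------------------------- folder I/O

_EXPORTS = {
    "gaze": ("gaze.csv", {
        "timestamp": "timestamp [ns]", "x": "gaze x [px]", "y": "gaze y [px]",
        "worn": "worn", "fixation_id": "fixation id", "blink_id": "blink id"}),
    "fixations": ("fixations.csv", {
        "id": "fixation id", "start_ts": "start timestamp [ns]",
        "end_ts": "end timestamp [ns]", "duration_ms": "duration [ms]",
        "cx": "fixation x [px]", "cy": "fixation y [px]"}),
    "blinks": ("blinks.csv", {
        "id": "blink id", "start_ts": "start timestamp [ns]",
        "end_ts": "end timestamp [ns]", "duration_ms": "duration [ms]"}),
    "saccades": ("saccades.csv", {
        "id": "saccade id", "start_ts": "start timestamp [ns]",
        "end_ts": "end timestamp [ns]", "duration_ms": "duration [ms]",
        "amplitude_px": "amplitude [px]", "mean_velocity": "mean velocity [px/s]",
        "peak_velocity": "peak velocity [px/s]"}),
    "pupil": ("3d_eye_states.csv", {
        "timestamp": "timestamp [ns]",
        "diameter_left": "pupil diameter left [mm]",
        "diameter_right": "pupil diameter right [mm]"}),
    "events": ("events.csv", {"name": "name", "timestamp": "timestamp [ns]"}),
    "surface_gaze": ("enrichment_gaze.csv", {
        "timestamp": "timestamp [ns]",
        "on_surface": "gaze detected on surface",
        "sx": "gaze position on surface x [normalized]",
        "sy": "gaze position on surface y [normalized]"}),
    "surface_fixations": ("enrichment_fixations.csv", {
        "timestamp": "timestamp [ns]",
        "on_surface": "fixation detected on surface",
        "sx": "fixation x [normalized]",
        "sy": "fixation y [normalized]"}),
}


def write_recording_folder(rec: Recording, folder: str | Path,
                           manifest: dict | None = None) -> Path:
    """Write *rec* as a cloud-dialect export folder (plus manifest.json).

    Deterministic: the same recording always produces byte-identical
    files.
    """
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    for stream, (fname, colmap) in _EXPORTS.items():
        df = getattr(rec, stream)
        out = df[list(colmap)].rename(columns=colmap).copy()
        for col in out.columns:
            if out[col].dtype == bool:
                out[col] = out[col].map({True: "true", False: "false"})
        out.to_csv(folder / fname, index=False, na_rep="",
                   lineterminator="\n")
    if manifest is not None:
        (folder / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8")
    return folder


def load_manifest(folder: str | Path) -> dict:
    return json.loads((Path(folder) / "manifest.json").read_text(encoding="utf-8"))
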