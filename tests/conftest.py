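"""Shared fixtures: deterministic scripted recordings and small simulations."""

from __future__ import annotations

import dataclasses

import pytest

from gazelab.movements import index_movements
from gazelab.roi import annotate_recording
from gazelab.synth import (SimulationConfig, generate_recording,
                           scripted_recording)

NS = 10 ** 9


def s2ns(t: float) -> int:
    return round(t * NS)


@pytest.fixture(scope="session")
def oracle_script() -> dict:
    """A fully hand-computable session: 3 fixations, 2 saccades, 3 blinks.

    100 Hz sampling over 10 s; ROI on for the first 6.5 s only, so the
    first two blinks are on-ROI and the third is not.
    """
    return {
        "duration_s": 10.0,
        "gaze_rate_hz": 100.0,
        "pupil_baseline_mm": 3.0,
        "fixations": [
            (1, s2ns(1.0), s2ns(2.0), 0.0, 0.0),
            (2, s2ns(2.1), s2ns(3.0), 300.0, 400.0),
            (3, s2ns(3.1), s2ns(4.6), 300.0, 1000.0),
        ],
        "blinks": [
            (1, s2ns(5.0), s2ns(5.1)),
            (2, s2ns(6.0), s2ns(6.15)),
            (3, s2ns(7.0), s2ns(7.2)),
        ],
        "roi_schedule": [(0.0, 6.5, True)],
    }


@pytest.fixture(scope="session")
def oracle_rec(oracle_script):
    rec, manifest = scripted_recording(oracle_script)
    return rec, manifest


@pytest.fixture(scope="session")
def counting_script() -> dict:
    """12 equally spaced fixations, 7 late blinks; continuous sampling."""
    return {
        "duration_s": 6.0,
        "gaze_rate_hz": 200.0,
        "fixations": [
            (i, s2ns(i * 0.4), s2ns(i * 0.4 + 0.3), 100.0 * i, 50.0 * i)
            for i in range(1, 13)
        ],
        "blinks": [
            (j, s2ns(5.0 + j * 0.12), s2ns(5.0 + j * 0.12 + 0.05))
            for j in range(1, 8)
        ],
    }


@pytest.fixture(scope="session")
def counting_rec(counting_script):
    rec, manifest = scripted_recording(counting_script)
    return rec, manifest


@pytest.fixture(scope="session")
def sim_rec():
    """One stochastic 30 s session at the generator defaults."""
    rec, manifest = generate_recording(SimulationConfig(duration_s=30.0, seed=7))
    return rec, manifest


@pytest.fixture(scope="session")
def sim_rec_annotated(sim_rec):
    rec, manifest = sim_rec
    rec = annotate_recording(rec)
    rec = dataclasses.replace(rec, gaze=index_movements(rec.gaze))
    return rec, manifest
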