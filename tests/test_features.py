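"""Feature battery, descriptive statistics, filtering, and the t-test."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gazelab as gl
from gazelab.features import (DEFAULT_BLINK_THRESHOLD, FeatureReport, Point2D,
                              blink_features, descriptive_stats,
                              euclidean_distance, filter_epochs_by_blinks,
                              fixation_features, pupil_features,
                              saccade_features, two_sample_ttest)
from gazelab.model import Epoch
from gazelab.movements import index_movements
from gazelab.roi import annotate_recording
from gazelab.synth import scripted_recording

NS = 10 ** 9


class TestPrimitives:
    def test_euclidean_three_four_five(self):
        assert euclidean_distance(Point2D(0, 0), Point2D(3, 4)) == 5.0

    def test_euclidean_identity(self):
        p = Point2D(2.5, -1.5)
        assert euclidean_distance(p, p) == 0.0

    def test_euclidean_mixed_frames_error(self):
        with pytest.raises(ValueError, match="frame"):
            euclidean_distance(Point2D(0, 0, "px"), Point2D(1, 1, "norm"))

    @settings(max_examples=50, deadline=None)
    @given(st.tuples(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3),
                     st.floats(-1e3, 1e3), st.floats(-1e3, 1e3)))
    def test_euclidean_matches_direct_formula(self, coords):
        x1, y1, x2, y2 = coords
        got = euclidean_distance(Point2D(x1, y1), Point2D(x2, y2))
        assert got == pytest.approx(math.sqrt((x2 - x1) ** 2 + (y2 - y1) ** 2),
                                    abs=1e-12)

    def test_descriptive_stats_constant_list(self):
        d = descriptive_stats([2, 2, 2])
        assert (d.mean, d.std, d.count, d.total) == (2.0, 0.0, 3, 6.0)

    def test_descriptive_stats_population_form(self):
        """[1,2,3]: population std is sqrt(2/3), not the sample form."""
        d = descriptive_stats([1, 2, 3])
        assert d.mean == 2.0
        assert d.std == pytest.approx(math.sqrt(2.0 / 3.0), abs=1e-12)

    def test_descriptive_stats_empty_errors(self):
        with pytest.raises(ValueError):
            descriptive_stats([])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=20),
           st.floats(-10, 10))
    def test_descriptive_stats_order_and_scaling(self, values, c):
        d = descriptive_stats(values)
        assert d.minimum - 1e-9 <= d.mean <= d.maximum + 1e-9
        scaled = descriptive_stats([c * v for v in values])
        assert scaled.std == pytest.approx(abs(c) * d.std, abs=1e-6)


def _blink_slice(durations_ms, on_roi):
    blinks = pd.DataFrame({
        "id": pd.array(range(1, len(durations_ms) + 1), dtype="Int64"),
        "start_ts": np.arange(len(durations_ms), dtype="int64") * NS,
        "end_ts": np.arange(len(durations_ms), dtype="int64") * NS
        + (np.asarray(durations_ms) * 1e6).astype("int64"),
        "duration_ms": np.asarray(durations_ms, float),
        "on_roi": on_roi,
    })
    return dataclasses.replace(gl.Recording(), blinks=blinks)


class TestCategoryExtractors:
    def test_blink_features_hand_fixture(self):
        """3 blinks of 100/150/200 ms, first two on-ROI."""
        out = blink_features(_blink_slice([100, 150, 200], [True, True, False]))
        assert out == {"count": 3, "duration_total_ms": 450.0,
                       "duration_mean_ms": 150.0, "duration_on_roi_ms": 250.0}

    def test_blink_features_no_blinks_all_zero(self):
        out = blink_features(_blink_slice([], []))
        assert out == {"count": 0, "duration_total_ms": 0.0,
                       "duration_mean_ms": 0.0, "duration_on_roi_ms": 0.0}

    def test_blink_surface_equals_total_when_all_on_roi(self):
        out = blink_features(_blink_slice([80, 120], [True, True]))
        assert out["duration_on_roi_ms"] == out["duration_total_ms"]

    def test_fixation_collinear_distances(self):
        """Centroids at x = 0, 10, 30 on one line: total 30, mean 15."""
        script = {
            "duration_s": 2.0,
            "fixations": [(1, 0, int(0.2e9), 0.0, 5.0),
                          (2, int(0.3e9), int(0.7e9), 10.0, 5.0),
                          (3, int(0.8e9), int(1.1e9), 30.0, 5.0)],
        }
        rec, _ = scripted_recording(script)
        out = fixation_features(rec)
        assert out["distance_total_px"] == pytest.approx(30.0, abs=1e-9)
        assert out["distance_mean_px"] == pytest.approx(15.0, abs=1e-9)
        assert out["count"] == 3
        # durations 200/400/300 ms: the longest fixation is the middle one
        assert (out["longest_x_px"], out["longest_y_px"]) == (10.0, 5.0)
        assert out["duration_max_ms"] == pytest.approx(400.0, abs=1e-6)

    def test_single_fixation_marks_distances_empty(self):
        script = {"duration_s": 1.0,
                  "fixations": [(1, 0, int(0.5e9), 1.0, 1.0)]}
        rec, _ = scripted_recording(script)
        out = fixation_features(rec)
        assert out["count"] == 1
        assert math.isnan(out["distance_total_px"])

    def test_saccade_features_peak_is_max_of_peaks(self):
        sac = pd.DataFrame({
            "id": pd.array([1, 2, 3], dtype="Int64"),
            "start_ts": np.asarray([0, NS, 2 * NS], "int64"),
            "end_ts": np.asarray([NS // 10, NS + NS // 10, 2 * NS + NS // 10], "int64"),
            "duration_ms": [100.0, 100.0, 100.0],
            "amplitude_px": [10.0, 20.0, 30.0],
            "mean_velocity": [100.0, 200.0, 300.0],
            "peak_velocity": [300.0, 500.0, 400.0],
        })
        out = saccade_features(dataclasses.replace(gl.Recording(), saccades=sac))
        assert out["peak_velocity_px_s"] == 500.0
        assert out["amplitude_mean_px"] == 20.0
        assert out["count"] == 3

    def test_no_saccades_empty_marked(self):
        out = saccade_features(gl.Recording())
        assert out["count"] == 0
        assert math.isnan(out["duration_total_ms"])

    def test_pupil_constant_series(self):
        pupil = pd.DataFrame({"timestamp": np.arange(5, dtype="int64") * NS,
                              "diameter_left": 3.0, "diameter_right": 3.0,
                              "diameter": 3.0})
        out = pupil_features(dataclasses.replace(gl.Recording(), pupil=pupil))
        for k in ("diameter_first_mm", "diameter_last_mm", "diameter_max_mm",
                  "diameter_min_mm", "diameter_mean_mm"):
            assert out[k] == 3.0

    def test_pupil_ramp_first_last(self):
        pupil = pd.DataFrame({"timestamp": np.arange(5, dtype="int64") * NS,
                              "diameter_left": np.linspace(2, 4, 5),
                              "diameter_right": np.linspace(2, 4, 5),
                              "diameter": np.linspace(2, 4, 5)})
        out = pupil_features(dataclasses.replace(gl.Recording(), pupil=pupil))
        assert out["diameter_first_mm"] == 2.0
        assert out["diameter_last_mm"] == 4.0

    def test_pupil_on_roi_restriction(self):
        pupil = pd.DataFrame({"timestamp": np.arange(4, dtype="int64") * NS,
                              "diameter_left": [2.0, 2.0, 4.0, 4.0],
                              "diameter_right": [2.0, 2.0, 4.0, 4.0],
                              "diameter": [2.0, 2.0, 4.0, 4.0],
                              "on_roi": [True, True, False, False]})
        sl = dataclasses.replace(gl.Recording(), pupil=pupil)
        assert pupil_features(sl, on_roi_only=True)["diameter_mean_mm"] == 2.0
        assert pupil_features(sl)["diameter_mean_on_roi_mm"] == 2.0


class TestReport:
    def test_grid_is_complete(self, sim_rec_annotated):
        rec, _ = sim_rec_annotated
        epochs = [Epoch("a", 0, 15 * NS), Epoch("b", 15 * NS, 30 * NS)]
        report = gl.extract_report(rec, epochs, "P01")
        combos = report.table.groupby(["epoch", "category"]).size()
        assert len(combos) == 2 * 6  # 5 stream categories + epoch meta

    def test_additive_indices_conserved_over_partition(self, sim_rec_annotated):
        """A 2-epoch partition sums to the whole-recording value for
        counts and duration totals."""
        rec, _ = sim_rec_annotated
        lo, hi = rec.span()
        whole = gl.extract_report(rec, [Epoch("all", lo, hi + 1)], "P")
        cut = (lo + hi) // 2
        parts = gl.extract_report(
            rec, [Epoch("a", lo, cut), Epoch("b", cut, hi + 1)], "P")
        for cat, idx in [("blink", "count"), ("blink", "duration_total_ms"),
                         ("blink", "duration_on_roi_ms"),
                         ("fixation", "count"), ("fixation", "duration_total_ms"),
                         ("saccade", "count"), ("saccade", "duration_total_ms"),
                         ("gaze", "sample_count"), ("pupil", "sample_count")]:
            total = whole.value(whole.epochs()[0], cat, idx)
            split = sum(parts.value(e, cat, idx) for e in parts.epochs())
            assert split == pytest.approx(total, abs=1e-6), (cat, idx)

    def test_report_is_deterministic(self, sim_rec_annotated):
        rec, _ = sim_rec_annotated
        epochs = gl.build_epochs(rec.events)
        r1 = gl.extract_report(rec, epochs, "P")
        r2 = gl.extract_report(rec, epochs, "P")
        pd.testing.assert_frame_equal(r1.table, r2.table)


def _report_with_blink_counts(counts):
    rows = []
    for i, c in enumerate(counts):
        rows.append((f"e{i}", "blink", "count", float(c), ""))
        rows.append((f"e{i}", "blink", "duration_total_ms", 100.0 * c, "ms"))
    return FeatureReport("P", pd.DataFrame(
        rows, columns=["epoch", "category", "index", "value", "units"]))


class TestBlinkFilter:
    def test_strictly_greater_than_threshold_excluded(self):
        """Counts [0,3,5,6,9] at threshold 5: keep 0/3/5, drop 6/9."""
        report = _report_with_blink_counts([0, 3, 5, 6, 9])
        filtered, excluded = filter_epochs_by_blinks(report, threshold=5)
        assert filtered.epochs() == ["e0", "e1", "e2"]
        assert excluded == [("e3", 6), ("e4", 9)]

    def test_default_threshold_is_five(self):
        assert DEFAULT_BLINK_THRESHOLD == 5

    def test_infinite_threshold_is_identity(self):
        report = _report_with_blink_counts([0, 3, 5, 6, 9])
        filtered, excluded = filter_epochs_by_blinks(report, threshold=np.inf)
        assert filtered.epochs() == report.epochs() and excluded == []

    def test_all_excluded_gives_empty_report_full_log(self):
        report = _report_with_blink_counts([7, 8])
        filtered, excluded = filter_epochs_by_blinks(report, threshold=5)
        assert filtered.epochs() == [] and len(excluded) == 2


def _pooled_t(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    return (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))


class TestTTest:
    def test_identical_groups_give_zero(self):
        res = two_sample_ttest([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0

    def test_degenerate_zero_variance_groups(self):
        res = two_sample_ttest([2, 2, 2], [2, 2, 2])
        assert (res.t, res.p) == (0.0, 1.0)

    def test_antisymmetry(self):
        a, b = [1.0, 2.0, 3.5], [2.0, 3.0, 4.0, 5.0]
        assert two_sample_ttest(a, b).t == pytest.approx(-two_sample_ttest(b, a).t)

    def test_matches_pooled_formula(self):
        a, b = [1, 2, 3], [2, 3, 4]
        res = two_sample_ttest(a, b)
        assert res.t == pytest.approx(_pooled_t(a, b), abs=1e-10)
        assert res.df == 4

    def test_welch_option_differs_under_unequal_variance(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 10)
        b = rng.normal(1, 5, 40)
        student = two_sample_ttest(a, b, equal_var=True)
        welch = two_sample_ttest(a, b, equal_var=False)
        assert student.df == 48
        assert welch.df != student.df

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            two_sample_ttest([1], [2, 3])
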