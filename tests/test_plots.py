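"""Prepared-plot content checks; rendering is exercised only thinly."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gazelab.plots import (blink_series_integral_ms, prepare_blink_series,
                           prepare_fixation_cloud, prepare_histogram,
                           prepare_path, prepare_pupil_roi_series,
                           prepare_saccade_series, render_figure)

NS = 10 ** 9
MS = 10 ** 6


def _pupil(flags):
    n = len(flags)
    return pd.DataFrame({"timestamp": np.arange(n, dtype="int64") * 5 * MS,
                         "diameter": 3.0 + 0.01 * np.arange(n),
                         "on_roi": flags})


class TestPupilSeries:
    def test_all_on_gives_single_green_segment(self):
        plot = prepare_pupil_roi_series(_pupil([True] * 10))
        assert [s["color"] for s in plot.annotations["segments"]] == ["green"]

    def test_segment_count_matches_transitions(self):
        flags = [True] * 5 + [False] * 5 + [True] * 5 + [False] * 5
        plot = prepare_pupil_roi_series(_pupil(flags))
        assert len(plot.annotations["segments"]) == 4  # 3 transitions + 1
        colors = [s["color"] for s in plot.annotations["segments"]]
        assert colors == ["green", "red", "green", "red"]

    def test_unannotated_or_empty_is_error(self):
        with pytest.raises(ValueError):
            prepare_pupil_roi_series(_pupil([]))
        with pytest.raises(ValueError):
            prepare_pupil_roi_series(_pupil([True]).drop(columns=["on_roi"]))


def _blinks(spans_ms):
    return pd.DataFrame({
        "id": pd.array(range(1, len(spans_ms) + 1), dtype="Int64"),
        "start_ts": np.asarray([s * MS for s, _ in spans_ms], "int64"),
        "end_ts": np.asarray([e * MS for _, e in spans_ms], "int64"),
        "duration_ms": [float(e - s) for s, e in spans_ms],
    })


class TestBlinkSeries:
    def test_three_blinks_make_three_pulses(self):
        plot = prepare_blink_series(_blinks([(10, 20), (40, 55), (70, 90)]),
                                    span=(0, 100 * MS))
        v = plot.series["blink"]
        rises = int(np.sum((v[1:] == 1) & (v[:-1] == 0)))
        assert rises == 3 and plot.annotations["n_blinks"] == 3

    def test_integral_equals_total_blink_duration(self):
        blinks = _blinks([(10, 20), (40, 55), (70, 90)])
        plot = prepare_blink_series(blinks, span=(0, 100 * MS))
        assert blink_series_integral_ms(plot) == pytest.approx(
            blinks["duration_ms"].sum(), abs=1e-6)

    def test_no_blinks_constant_zero(self):
        plot = prepare_blink_series(_blinks([]), span=(0, NS))
        assert np.all(plot.series["blink"] == 0)


class TestSaccadeSeries:
    @pytest.fixture()
    def saccades(self):
        return pd.DataFrame({
            "id": pd.array([1, 2], dtype="Int64"),
            "start_ts": np.asarray([0, NS], "int64"),
            "end_ts": np.asarray([NS // 10, NS + NS // 10], "int64"),
            "duration_ms": [100.0, 100.0],
            "amplitude_px": [50.0, 80.0],
            "mean_velocity": [1000.0, 2000.0],
            "peak_velocity": [1800.0, 3600.0],
        })

    def test_peak_dominates_mean_pointwise(self, saccades):
        plot = prepare_saccade_series(saccades, "velocity")
        assert np.all(plot.series["peak_velocity_px_ms"]
                      >= plot.series["mean_velocity_px_ms"])

    def test_unit_conversion_divides_by_thousand(self, saccades):
        plot = prepare_saccade_series(saccades, "velocity")
        assert plot.series["mean_velocity_px_ms"].tolist() == [1.0, 2.0]
        assert "px/ms" in plot.annotations["ylabel"]

    def test_amplitude_round_trips_exactly(self, saccades):
        plot = prepare_saccade_series(saccades, "amplitude")
        assert plot.series["amplitude_px"].tolist() == [50.0, 80.0]

    def test_empty_is_flagged_not_fatal(self):
        plot = prepare_saccade_series(pd.DataFrame(), "velocity")
        assert plot.annotations.get("empty")


class TestFixationCloud:
    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(4)
        pts = rng.normal([500, 400], 40, (300, 2))
        plot = prepare_fixation_cloud(pts)
        mass = plot.series["density"].sum() * plot.annotations["cell_area"]
        assert mass == pytest.approx(1.0, abs=0.02)

    def test_two_clusters_give_two_modes_near_centroids(self):
        rng = np.random.default_rng(9)
        a = rng.normal([200, 200], 15, (200, 2))
        b = rng.normal([900, 800], 15, (200, 2))
        plot = prepare_fixation_cloud(np.vstack([a, b]))
        d = plot.series["density"]
        gx, gy = plot.series["grid_x"], plot.series["grid_y"]
        iy, ix = np.unravel_index(np.argmax(d), d.shape)
        first_mode = np.array([gx[ix], gy[iy]])
        # suppress the found mode's half-plane and find the second
        half = d.copy()
        if first_mode[0] < 550:
            half[:, gx < 550] = 0
        else:
            half[:, gx >= 550] = 0
        jy, jx = np.unravel_index(np.argmax(half), half.shape)
        second_mode = np.array([gx[jx], gy[jy]])
        modes = sorted([first_mode, second_mode], key=lambda m: m[0])
        assert np.allclose(modes[0], [200, 200], atol=30)
        assert np.allclose(modes[1], [900, 800], atol=30)

    def test_single_point_degrades_to_scatter(self, caplog):
        with caplog.at_level("WARNING"):
            plot = prepare_fixation_cloud(np.array([[1.0, 2.0]]))
        assert plot.annotations["density"] is False


class TestPathAndHistogram:
    def test_collinear_polyline_length(self):
        pts = np.array([[0, 0], [10, 0], [30, 0]], float)
        plot = prepare_path(pts, mode="absolute")
        assert plot.annotations["total_length"] == pytest.approx(30.0)

    def test_relative_mode_labels_normalised_units(self):
        pts = np.array([[0.1, 0.2], [0.5, 0.9]])
        plot = prepare_path(pts, mode="relative")
        assert np.all((plot.series["x"] >= 0) & (plot.series["x"] <= 1))
        assert "norm" in plot.annotations["xlabel"]

    def test_reversal_preserves_geometry(self):
        pts = np.array([[0, 0], [3, 4], [10, 2]], float)
        fwd = prepare_path(pts)
        rev = prepare_path(pts[::-1])
        assert fwd.annotations["total_length"] == pytest.approx(
            rev.annotations["total_length"])
        assert np.allclose(rev.series["x"], fwd.series["x"][::-1])

    def test_too_few_points_is_error(self):
        with pytest.raises(ValueError):
            prepare_path(np.array([[1.0, 1.0]]))

    def test_histogram_counts_sum_to_n(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, 500)
        plot = prepare_histogram(vals, bins=20)
        assert plot.series["counts"].sum() == 500

    def test_degenerate_histogram_single_occupied_bin(self):
        plot = prepare_histogram([5.0] * 50, bins=10)
        assert np.count_nonzero(plot.series["counts"]) == 1

    def test_uniform_fixture_bins_within_three_sigma(self):
        rng = np.random.default_rng(6)
        n, bins = 10_000, 10
        plot = prepare_histogram(rng.uniform(0, 1, n), bins=bins)
        expect = n / bins
        sigma = np.sqrt(n * (1 / bins) * (1 - 1 / bins))
        assert np.all(np.abs(plot.series["counts"] - expect) <= 3.5 * sigma)


class TestRendering:
    def test_rendered_file_is_non_empty(self, tmp_path):
        plot = prepare_histogram([1.0, 2.0, 3.0], bins=5)
        out = render_figure(plot, tmp_path / "h.png")
        assert (tmp_path / "h.png").stat().st_size > 0

    def test_empty_allowed_plot_renders_placeholder(self, tmp_path):
        plot = prepare_saccade_series(pd.DataFrame(), "velocity")
        render_figure(plot, tmp_path / "e.png")
        assert (tmp_path / "e.png").stat().st_size > 0

    def test_preparation_is_deterministic(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(0, 1, (100, 2))
        p1 = prepare_fixation_cloud(pts)
        p2 = prepare_fixation_cloud(pts)
        assert np.array_equal(p1.series["density"], p2.series["density"])
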