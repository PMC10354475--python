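import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Polygon

import fisfus as ff
from fisfus.errors import ConfigError, DataError
from fisfus.preprocess import (
    PreprocessConfig,
    exclude_intervals,
    filter_boundary,
    filter_satellites,
    filter_speed,
    regularize,
)

SQUARE = Polygon([(0, 0), (3000, 0), (3000, 2000), (0, 2000)])


def track(points, ident="a", dt=6.0):
    t = np.arange(len(points)) * dt
    xy = np.asarray(points, dtype=float)
    return pd.DataFrame({"id": ident, "time": t, "x": xy[:, 0], "y": xy[:, 1]})


class TestBoundary:
    def test_all_inside_unchanged(self):
        fixes = track([(10, 10), (20, 20), (30, 30)])
        out = filter_boundary(fixes, SQUARE)
        pd.testing.assert_frame_equal(out, fixes)

    def test_distant_outlier_removed(self):
        fixes = track([(10, 10), (1e6, 1e6), (30, 30)])
        out = filter_boundary(fixes, SQUARE)
        assert len(out) == 2
        assert 1e6 not in out["x"].values

    def test_fix_on_edge_retained(self):
        fixes = track([(0.0, 100.0), (3000.0, 100.0)])
        assert len(filter_boundary(fixes, SQUARE)) == 2

    def test_degenerate_polygon_rejected(self):
        line = Polygon([(0, 0), (1, 1), (2, 2)])
        with pytest.raises(ConfigError):
            filter_boundary(track([(0, 0)]), line)


class TestSatellites:
    def test_threshold_is_minimum_for_triangulation(self):
        fixes = track([(0, 0), (1, 0), (2, 0)])
        fixes["nsat"] = [2.0, 3.0, 7.0]
        out = filter_satellites(fixes, 3)
        assert list(out["nsat"]) == [3.0, 7.0]

    def test_all_good_unchanged(self):
        fixes = track([(0, 0), (1, 0)])
        fixes["nsat"] = [5.0, 4.0]
        assert len(filter_satellites(fixes, 3)) == 2

    def test_absent_column_retained_with_warning(self, caplog):
        fixes = track([(0, 0), (1, 0)])
        with caplog.at_level("WARNING", logger="fisfus"):
            out = filter_satellites(fixes, 3)
        assert len(out) == 2
        assert any("satellite" in r.message for r in caplog.records)


class TestSpeed:
    def test_single_spike_removed(self):
        # stationary-ish track; one fix 100 m off is 16.7 m/s both ways
        pts = [(k * 3.0, 0.0) for k in range(7)]
        fixes = track(pts)
        fixes.loc[3, "y"] = 100.0
        out = filter_speed(fixes, 1.5)
        assert len(out) == 6
        assert (out["y"] == 0.0).all()

    def test_genuine_run_at_vmax_untouched(self):
        pts = [(k * 6.0, 0.0) for k in range(20)]  # 1.0 m/s
        fixes = track(pts)
        out = filter_speed(fixes, 1.5)
        assert len(out) == 20

    def test_two_consecutive_spikes_removed_after_iteration(self):
        # two spikes on opposite sides of the track are also mutually
        # unreachable, so iterative application removes both
        pts = [(k * 3.0, 0.0) for k in range(8)]
        fixes = track(pts)
        fixes.loc[3, "y"] = 100.0
        fixes.loc[4, "y"] = -100.0
        out = filter_speed(fixes, 1.5)
        assert len(out) == 6
        assert (out["y"] == 0.0).all()

    def test_brute_force_order_enumeration_agrees(self):
        """Final retained set equals brute-force exploration of removal orders."""
        pts = [(k * 3.0, 0.0) for k in range(8)]
        fixes = track(pts)
        fixes.loc[3, "y"] = 100.0
        fixes.loc[4, "y"] = -100.0
        t = fixes["time"].to_numpy()
        x = fixes["x"].to_numpy()
        y = fixes["y"].to_numpy()

        def removable(kept):
            out = []
            for pos, i in enumerate(kept):
                prevs = kept[max(0, pos - 2) : pos]
                nexts = kept[pos + 1 : pos + 3]
                if not prevs and not nexts:
                    continue

                def unreach(j):
                    d = np.hypot(x[i] - x[j], y[i] - y[j])
                    return d > 1.5 * abs(t[i] - t[j])

                if all(unreach(j) for j in prevs) and all(unreach(j) for j in nexts):
                    out.append(i)
            return out

        finals = set()

        def explore(kept):
            rem = removable(kept)
            if not rem:
                finals.add(tuple(kept))
                return
            for i in rem:
                explore([k for k in kept if k != i])

        explore(list(range(8)))
        assert finals == {(0, 1, 2, 5, 6, 7)}
        out = filter_speed(fixes, 1.5)
        assert list(out.index) == list(range(6))
        assert (out["y"] == 0.0).all()

    def test_non_monotone_times_rejected(self):
        fixes = track([(0, 0), (1, 0), (2, 0)])
        fixes.loc[2, "time"] = 3.0
        with pytest.raises(DataError):
            filter_speed(fixes, 1.5)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_compliant_track_never_touched(self, seed):
        """No fix is removed from a track whose every consecutive implied
        speed is within v_max."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        dt = 6.0
        headings = rng.uniform(0, 2 * np.pi, n - 1)
        speeds = rng.uniform(0, 1.5, n - 1)
        steps = (speeds * dt)[:, None] * np.column_stack(
            [np.cos(headings), np.sin(headings)]
        )
        xy = np.vstack([[0.0, 0.0], steps.cumsum(axis=0)])
        fixes = track(xy)
        out = filter_speed(fixes, 1.5)
        assert len(out) == n


class TestRegularize:
    def test_linear_midpoint(self):
        fixes = track([(0, 0)]).iloc[:0]
        fixes = pd.DataFrame(
            {"id": ["a", "a"], "time": [0.0, 12.0], "x": [0.0, 12.0], "y": [0.0, 0.0]}
        )
        traj = regularize(fixes, PreprocessConfig(), t0=0.0, t_end=12.0)
        assert traj.n_steps == 3
        np.testing.assert_allclose(traj.xy[0, 1], [6.0, 0.0])

    def test_gap_longer_than_max_gap_stays_missing(self):
        fixes = pd.DataFrame(
            {"id": ["a", "a"], "time": [0.0, 24.0], "x": [0.0, 24.0], "y": [0.0, 0.0]}
        )
        traj = regularize(fixes, PreprocessConfig(max_gap=2), t0=0.0, t_end=24.0)
        assert list(traj.present()[0]) == [True, False, False, False, True]

    def test_short_gap_is_interpolated(self):
        fixes = pd.DataFrame(
            {"id": ["a", "a"], "time": [0.0, 18.0], "x": [0.0, 18.0], "y": [0.0, 0.0]}
        )
        traj = regularize(fixes, PreprocessConfig(max_gap=2), t0=0.0, t_end=18.0)
        assert traj.present()[0].all()
        np.testing.assert_allclose(traj.xy[0, :, 0], [0.0, 6.0, 12.0, 18.0])

    def test_single_fix_populates_nearest_step_only(self):
        fixes = pd.DataFrame({"id": ["a"], "time": [7.0], "x": [3.0], "y": [4.0]})
        traj = regularize(fixes, PreprocessConfig(), t0=0.0, t_end=18.0)
        assert list(traj.present()[0]) == [False, True, False, False]
        np.testing.assert_allclose(traj.xy[0, 1], [3.0, 4.0])

    def test_no_extrapolation_beyond_track(self):
        fixes = pd.DataFrame(
            {"id": ["a", "a"], "time": [12.0, 18.0], "x": [1.0, 2.0], "y": [0.0, 0.0]}
        )
        traj = regularize(fixes, PreprocessConfig(), t0=0.0, t_end=36.0)
        present = traj.present()[0]
        assert not present[0]
        assert not present[-1]

    def test_empty_table_warns(self, caplog):
        with caplog.at_level("WARNING", logger="fisfus"):
            traj = regularize(pd.DataFrame(columns=["id", "time", "x", "y"]))
        assert traj.n_individuals == 0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_idempotent_on_regular_data(self, seed):
        """Feeding a regularized trajectory's implied fixes back through
        regularize reproduces it exactly."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        t = np.sort(rng.uniform(0.0, 300.0, n))
        t = t[np.diff(t, prepend=-1.0) > 0.5]
        fixes = pd.DataFrame(
            {
                "id": "a",
                "time": t,
                "x": rng.normal(0, 50, t.size),
                "y": rng.normal(0, 50, t.size),
            }
        )
        cfg = PreprocessConfig()
        traj = regularize(fixes, cfg, t0=0.0, t_end=300.0)
        again = regularize(traj.to_fixes(), cfg, t0=0.0, t_end=300.0)
        assert again == traj


def test_exclude_intervals_masks_half_open_ranges():
    fixes = track([(k, 0) for k in range(10)])
    out = exclude_intervals(fixes, [(12.0, 24.0)])
    assert list(out["time"]) == [0.0, 6.0, 24.0, 30.0, 36.0, 42.0, 48.0, 54.0]


def test_config_validation():
    with pytest.raises(ConfigError):
        PreprocessConfig(v_max=0.0)
    with pytest.raises(ConfigError):
        PreprocessConfig(max_gap=-1)
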