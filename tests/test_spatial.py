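import numpy as np
import pandas as pd
import pytest

import fisfus as ff
from fisfus.errors import ConfigError, DataError
from fisfus.simulate import synthetic_cell_hour_table, synthetic_occupancy_table
from fisfus.spatial import (
    Grid,
    distance_to_resource,
    event_cell_counts,
    fit_cell_hour_model,
    normalized_rate,
    occupancy,
    pearson,
)


def stationary_traj(x, y, n_steps, ident="a"):
    xy = np.zeros((1, n_steps, 2))
    xy[0, :, 0] = x
    xy[0, :, 1] = y
    return ff.TrajectorySet([ident], 0.0, 6.0, xy)


class TestGrid:
    def test_from_bounds_anchors_to_cell_size(self):
        g = Grid.from_bounds(12.0, 267.0, 480.0, 520.0, 50.0)
        assert (g.x0, g.y0) == (0.0, 250.0)
        assert g.n_cols == 10 and g.n_rows == 6

    def test_boundary_point_assigned_upward(self):
        g = Grid(0.0, 0.0, 50.0, 4, 4)
        col, row = g.cell_index(50.0, 100.0)
        assert (col, row) == (1, 2)


class TestOccupancy:
    def test_stationary_animal_fills_one_cell(self):
        traj = stationary_traj(25.0, 25.0, 100)
        g = Grid(0.0, 0.0, 50.0, 2, 2)
        counts, overflow = occupancy(traj, g)
        assert counts[0, 0] == 100
        assert counts.sum() == 100 and overflow == 0

    def test_total_occupancy_is_number_of_present_cells(self, jitter_traj):
        g = Grid.from_traj(jitter_traj, 50.0)
        counts, overflow = occupancy(jitter_traj, g)
        assert counts.sum() + overflow == jitter_traj.present().sum()

    def test_positions_outside_grid_flagged(self, caplog):
        traj = stationary_traj(500.0, 500.0, 10)
        g = Grid(0.0, 0.0, 50.0, 2, 2)
        with caplog.at_level("WARNING", logger="fisfus"):
            counts, overflow = occupancy(traj, g)
        assert overflow == 10 and counts.sum() == 0


class TestEventCellCounts:
    def _events(self, locations):
        evs = [
            ff.Event(
                kind="fission",
                step=k,
                clock_time=k * 6.0,
                x=x,
                y=y,
                reference=frozenset({"a", "b"}),
                branches=(frozenset({"a"}), frozenset({"b"})),
            )
            for k, (x, y) in enumerate(locations)
        ]
        return ff.EventList(evs)

    def test_no_events_all_zero(self):
        g = Grid(0.0, 0.0, 50.0, 2, 2)
        counts, overflow = event_cell_counts(self._events([]), g)
        assert counts.sum() == 0 and overflow == 0

    def test_three_events_in_one_cell(self):
        g = Grid(0.0, 0.0, 50.0, 2, 2)
        counts, _ = event_cell_counts(self._events([(10, 10)] * 3), g)
        assert counts[0, 0] == 3

    def test_sum_equals_located_events(self, caplog):
        g = Grid(0.0, 0.0, 50.0, 4, 4)
        locs = [(10, 10), (60, 60), (110, 20), (float("nan"), float("nan"))]
        with caplog.at_level("WARNING", logger="fisfus"):
            counts, overflow = event_cell_counts(self._events(locs), g)
        assert counts.sum() + overflow == 3  # NaN event skipped


class TestResourceDistance:
    def test_resource_at_cell_center_gives_zero(self):
        g = Grid(0.0, 0.0, 50.0, 2, 2)
        res = pd.DataFrame({"label": ["water"], "x": [25.0], "y": [25.0]})
        d = distance_to_resource(g, res)
        assert d[0, 0] == 0.0

    def test_monotone_along_a_ray(self):
        g = Grid(0.0, 0.0, 50.0, 10, 1)
        res = pd.DataFrame({"label": ["food"], "x": [25.0], "y": [25.0]})
        d = distance_to_resource(g, res)[0]
        assert np.all(np.diff(d) > 0)

    def test_two_resources_take_per_cell_minimum(self):
        g = Grid(0.0, 0.0, 50.0, 8, 3)
        res = pd.DataFrame(
            {"label": ["food", "water"], "x": [25.0, 375.0], "y": [25.0, 125.0]}
        )
        d = distance_to_resource(g, res)
        centers = g.centers().reshape(-1, 2)
        brute = np.minimum(
            np.hypot(centers[:, 0] - 25.0, centers[:, 1] - 25.0),
            np.hypot(centers[:, 0] - 375.0, centers[:, 1] - 125.0),
        ).reshape(3, 8)
        np.testing.assert_allclose(d, brute)

    def test_empty_resources_rejected(self):
        g = Grid(0.0, 0.0, 50.0, 2, 2)
        with pytest.raises(ConfigError):
            distance_to_resource(g, pd.DataFrame(columns=["label", "x", "y"]))


class TestNormalizedRate:
    def test_rate_is_events_per_time_step(self):
        out = normalized_rate(np.array([5.0]), np.array([500.0]))
        assert out[0] == pytest.approx(0.01)

    def test_below_min_occupancy_is_missing(self):
        out = normalized_rate(np.array([5.0]), np.array([49.0]))
        assert np.isnan(out[0])

    def test_zero_events_is_zero_rate(self):
        out = normalized_rate(np.array([0.0]), np.array([500.0]))
        assert out[0] == 0.0


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_independent_large_n_near_zero(self):
        rng = np.random.default_rng(0)
        r, _ = pearson(rng.normal(size=5000), rng.normal(size=5000))
        assert abs(r) < 0.05

    def test_four_point_closed_form(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.0, 1.0, 2.0, 2.0])
        r, _ = pearson(x, y)
        # independent closed-form evaluation
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert r == pytest.approx(expected)

    def test_missing_pairs_dropped(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, np.nan])
        y = np.array([0.0, 1.0, 2.0, np.nan, 4.0])
        r, _ = pearson(x, y)
        assert r == pytest.approx(1.0)

    def test_zero_variance_signals(self):
        with pytest.raises(DataError):
            pearson(np.ones(5), np.arange(5.0))


class TestTranslationInvariance:
    def test_cell_stats_unchanged_under_shift(self, jitter_traj):
        shift = np.array([1234.0, -987.0])
        moved = ff.TrajectorySet(
            jitter_traj.ids, jitter_traj.t0, jitter_traj.dt, jitter_traj.xy + shift
        )
        g0 = Grid.from_bounds(0.0, -50.0, 150.0, 100.0, 50.0)
        g1 = Grid(
            g0.x0 + shift[0], g0.y0 + shift[1], g0.cell_size, g0.n_cols, g0.n_rows
        )
        c0, o0 = occupancy(jitter_traj, g0)
        c1, o1 = occupancy(moved, g1)
        assert np.array_equal(c0, c1) and o0 == o1


class TestMixedModel:
    def test_null_response_recovers_zero_effects(self):
        rng = np.random.default_rng(5)
        tab = synthetic_cell_hour_table(
            n_cells=100,
            beta_distance=0.0,
            beta_activity=0.0,
            beta_interaction=0.0,
            cell_sd=0.0,
            seed=5,
        )
        res = fit_cell_hour_model(tab, "raw")
        for name in ("distance", "activity", "distance:activity"):
            assert abs(res.params[name]) <= 3 * res.bse[name] + 0.05

    def test_known_coefficients_recovered_within_three_se(self):
        tab = synthetic_cell_hour_table(
            n_cells=200,
            beta_distance=-0.5,
            beta_activity=0.3,
            beta_interaction=0.0,
            cell_sd=0.2,
            seed=42,
        )
        res = fit_cell_hour_model(tab, "raw")
        assert res.used_random_effect and res.converged
        for name, truth in [
            ("distance", -0.5),
            ("activity", 0.3),
            ("distance:activity", 0.0),
        ]:
            assert abs(res.params[name] - truth) <= 3 * res.bse[name]
        assert res.group_var >= 0 and res.resid_var >= 0

    def test_duplicated_rows_keep_estimates_inflate_precision(self):
        tab = synthetic_cell_hour_table(n_cells=60, seed=7)
        res1 = fit_cell_hour_model(tab, "raw")
        res2 = fit_cell_hour_model(
            pd.concat([tab, tab], ignore_index=True), "raw"
        )
        for name in ("distance", "activity"):
            assert res2.params[name] == pytest.approx(res1.params[name], abs=0.02)
            assert res2.bse[name] < res1.bse[name]

    def test_single_cell_rejected(self):
        tab = synthetic_cell_hour_table(n_cells=1, seed=0)
        with pytest.raises(DataError):
            fit_cell_hour_model(tab, "raw")

    def test_summary_mentions_all_fixed_effects(self):
        tab = synthetic_cell_hour_table(n_cells=50, seed=3)
        text = fit_cell_hour_model(tab, "raw").summary()
        for name in ("distance", "activity", "distance:activity"):
            assert name in text


class TestOccupancyContrast:
    def test_uniform_event_rate_has_no_distance_signal_after_normalization(self):
        """Averaged over independent replicates (the per-draw correlation has
        sd ~ 1/sqrt(n_cells)), raw counts carry the occupancy gradient while
        the normalized rate does not."""
        raw, norm = [], []
        for seed in range(10):
            tab = synthetic_occupancy_table(n_cells=500, seed=seed)
            r_raw, _ = pearson(tab["event_count"], tab["distance"])
            rate = normalized_rate(
                tab["event_count"].to_numpy(), tab["occupancy"].to_numpy()
            )
            r_norm, _ = pearson(rate, tab["distance"])
            raw.append(r_raw)
            norm.append(r_norm)
        assert np.mean(raw) < -0.3
        assert abs(np.mean(norm)) < 0.05
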