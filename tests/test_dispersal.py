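"""Dispersal simulator: endpoints, start reconstruction, events, LDD."""

import numpy as np
import pandas as pd
import pytest

from deerseed import AnalysisConfig, Trajectory
from deerseed.dispersal import (kernel_summary, ldd_table, locate_start,
                                sample_endpoints, simulate_events,
                                simulate_events_exhaustive)

from conftest import make_trajectory


def cfg(**kw):
    defaults = dict(rng_seed=0, n_endpoint_draws=1000)
    defaults.update(kw)
    return AnalysisConfig(**defaults)


class TestSampleEndpoints:
    def test_endpoints_come_from_fixes(self, straight_walk):
        pts = sample_endpoints(straight_walk, 500, np.random.default_rng(0))
        assert set(pts["easting"]).issubset(set(straight_walk.easting))
        assert len(pts) == 500

    def test_seeded_draw_is_reproducible(self, straight_walk):
        a = sample_endpoints(straight_walk, 1, np.random.default_rng(5))
        b = sample_endpoints(straight_walk, 1, np.random.default_rng(5))
        assert a.equals(b)

    def test_uniformity_within_binomial_error(self):
        traj = make_trajectory(n_fixes=10)
        pts = sample_endpoints(traj, 100_000, np.random.default_rng(1))
        freq = pts["easting"].value_counts(normalize=True)
        sd = np.sqrt(0.1 * 0.9 / 100_000)
        assert (np.abs(freq - 0.1) < 3 * sd).all()

    def test_short_trajectory_raises(self):
        t = make_trajectory(n_fixes=2)
        one = Trajectory("x", t.times[:1], t.easting[:1], t.northing[:1],
                         t.elevation[:1])
        with pytest.raises(ValueError):
            sample_endpoints(one, 5, np.random.default_rng(0))


class TestLocateStart:
    def test_exact_fix_hit_returns_that_fix(self, straight_walk):
        pos = locate_start(straight_walk, straight_walk.times[3])
        assert pos == (straight_walk.easting[3], straight_walk.northing[3],
                       straight_walk.elevation[3])

    def test_midpoint_interpolates_linearly(self):
        t = make_trajectory(n_fixes=2, vx=1000.0, vz=100.0, z0=600.0)
        mid = t.times[0] + np.timedelta64(30 * 60, "s")
        pos = locate_start(t, mid)
        assert pos == pytest.approx((500.0, 0.0, 650.0))

    def test_before_first_fix_is_unresolved(self, straight_walk):
        early = straight_walk.times[0] - np.timedelta64(1, "s")
        assert locate_start(straight_walk, early) is None


class TestSimulateEvents:
    def test_stationary_trajectory_gives_zero_displacement(self):
        t0 = np.datetime64("2018-05-01T00:00", "ns")
        times = t0 + np.arange(50) * np.timedelta64(3600, "s")
        traj = Trajectory("still", times, np.full(50, 5.0), np.full(50, 7.0),
                          np.full(50, 600.0))
        ev, _ = simulate_events(traj, np.array([1.0, 5.0]), cfg(),
                                np.random.default_rng(0))
        assert (ev["d_horiz_m"] == 0).all()
        assert (ev["d_vert_m"] == 0).all()

    def test_constant_velocity_gives_d_equals_v_times_p(self):
        # straight east at 1000 m/h with p = 2 h: every d is exactly 2000 m
        traj = make_trajectory(n_fixes=200, vx=1000.0)
        ev, info = simulate_events(traj, np.array([2.0]), cfg(),
                                   np.random.default_rng(1))
        assert (ev["d_horiz_m"] == 2000.0).all()
        assert info.n_events + info.n_dropped == 1000

    def test_constant_climb_gives_vertical_closed_form(self):
        traj = make_trajectory(n_fixes=200, vx=100.0, vz=10.0)
        ev, _ = simulate_events(traj, np.array([6.0]), cfg(),
                                np.random.default_rng(2))
        np.testing.assert_allclose(ev["d_vert_m"], 60.0, atol=1e-9)

    def test_all_dropped_raises_helpful_error(self):
        traj = make_trajectory(n_fixes=3)
        with pytest.raises(ValueError, match="too short"):
            simulate_events(traj, np.array([100.0]), cfg(max_redraws=3),
                            np.random.default_rng(3))

    def test_month_comes_from_endpoint_timestamp(self):
        traj = make_trajectory(n_fixes=100, start="2018-05-30T00:00")
        ev, _ = simulate_events(traj, np.array([1.0]), cfg(),
                                np.random.default_rng(4))
        assert set(ev["month"]) <= {5, 6}

    def test_nearest_start_rule_snaps_to_fixes(self):
        traj = make_trajectory(n_fixes=100, vx=1000.0)
        ev, _ = simulate_events(traj, np.array([0.4]),
                                cfg(start_rule="nearest"),
                                np.random.default_rng(5))
        assert set(ev["start_e"]).issubset(set(traj.easting))


class TestExhaustiveOracle:
    def test_matches_bruteforce_enumeration(self):
        """LDD probabilities from the exhaustive simulator equal a from-
        scratch enumeration of every (endpoint fix, passage time) pair."""
        traj = make_trajectory(n_fixes=40, vx=347.0, vy=213.0, vz=7.0)
        p_set = np.array([0.5, 2.0, 3.7, 11.0, 26.0])
        c = cfg(horizontal_threshold=900.0, vertical_threshold=30.0)

        counts = {}
        ts = traj.t_seconds
        for i in range(len(traj)):
            for p in p_set:
                t_start = ts[i] - p * 3600
                if t_start < ts[0]:
                    continue
                e = np.interp(t_start, ts, traj.easting)
                n = np.interp(t_start, ts, traj.northing)
                z = np.interp(t_start, ts, traj.elevation)
                dh = np.hypot(traj.easting[i] - e, traj.northing[i] - n)
                dv = traj.elevation[i] - z
                month = pd.Timestamp(traj.times[i]).month
                key = (traj.animal_id, month)
                cell = counts.setdefault(key, [0, 0, 0, 0])
                cell[0] += dh > 900.0
                cell[1] += dv > 30.0
                cell[2] += dv < -30.0
                cell[3] += 1

        events = simulate_events_exhaustive(traj, p_set, c)
        table = ldd_table(events, c)
        assert len(table) == len(counts)
        for row in table.itertuples():
            hor, up, down, n = counts[(row.animal_id, row.month)]
            assert row.horizontal == hor / n
            assert row.upward == up / n
            assert row.downward == down / n
            assert row.n_events == n


class TestLddTable:
    def _events(self, dh, dv=None, month=6):
        dh = np.asarray(dh, dtype=float)
        dv = np.zeros_like(dh) if dv is None else np.asarray(dv, dtype=float)
        return pd.DataFrame({"animal_id": "a", "month": month,
                             "d_horiz_m": dh, "d_vert_m": dv})

    def test_enumerated_fraction(self):
        t = ldd_table(self._events([500, 1500, 800, 2000]), cfg())
        assert t.loc[0, "horizontal"] == 0.5
        assert t.loc[0, "n_events"] == 4

    def test_small_vertical_displacements_give_zero(self):
        t = ldd_table(self._events([0, 0], dv=[-49.9, 49.9]), cfg())
        assert t.loc[0, "upward"] == 0 and t.loc[0, "downward"] == 0

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(6)
        ev = self._events(rng.exponential(800, 500))
        probs = [ldd_table(ev, cfg(horizontal_threshold=th))
                 .loc[0, "horizontal"] for th in (100, 500, 1000, 3000)]
        assert (np.diff(probs) <= 0).all()

    def test_upward_plus_downward_at_most_one(self):
        rng = np.random.default_rng(7)
        ev = self._events(rng.exponential(500, 300),
                          dv=rng.normal(0, 80, 300))
        t = ldd_table(ev, cfg())
        assert (t["upward"] + t["downward"] <= 1).all()


class TestKernelSummary:
    def test_singleton(self):
        ev = pd.DataFrame({"animal_id": "a", "month": 6,
                           "d_horiz_m": [737.0], "d_vert_m": [0.0]})
        k = kernel_summary(ev, cfg())
        assert k["mean_horizontal_m"] == 737.0
        assert k["horizontal_q01_m"] == k["horizontal_q99_m"] == 737.0

    def test_two_event_fraction(self):
        ev = pd.DataFrame({"animal_id": "a", "month": 6,
                           "d_horiz_m": [0.0, 2000.0],
                           "d_vert_m": [0.0, 0.0]})
        assert kernel_summary(ev, cfg())["frac_horizontal_ldd"] == 0.5

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            kernel_summary(pd.DataFrame(columns=["d_horiz_m", "d_vert_m"]),
                           cfg())
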