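"""Zone occupancy, wall-stay curves, crossing analyses and path extraction."""

import numpy as np
import pytest

import larvakin as lk
from larvakin.thigmotaxis import ArenaGeometry

from conftest import make_trajectory, radial_trajectory


class TestArenaGeometry:
    def test_default_zone_areas(self):
        arena = ArenaGeometry()
        assert arena.inner_area_fraction == pytest.approx(0.36)
        assert arena.center_disc_radius == pytest.approx(7.5 * np.sqrt(0.05))

    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError):
            ArenaGeometry(inner_radius=8.0)
        with pytest.raises(ValueError):
            ArenaGeometry(edge_reach=2.0, edge_stay=1.0)


class TestZoneOccupancy:
    def test_random_reference_is_area_fraction(self, arena):
        occ = lk.zone_occupancy(radial_trajectory([1.0, 2.0]), arena)
        assert occ.random_outer_pct == pytest.approx(64.0)

    def test_center_dweller_is_all_inner(self, arena):
        occ = lk.zone_occupancy(radial_trajectory(np.zeros(10)), arena)
        assert occ.pct_inner == 100.0 and occ.pct_outer == 0.0

    def test_boundary_counts_as_outer(self, arena):
        occ = lk.zone_occupancy(radial_trajectory([4.5]), arena)
        assert occ.pct_outer == 100.0

    def test_percentages_sum_to_100(self, arena):
        rng = np.random.default_rng(1)
        r = 7.4 * np.sqrt(rng.random(1000))
        occ = lk.zone_occupancy(radial_trajectory(r), arena)
        assert occ.pct_inner + occ.pct_outer == pytest.approx(100.0)

    def test_uniform_monte_carlo_matches_area(self, arena):
        """1e6 area-uniform positions give 64.0 +/- 0.2% outer occupancy."""
        rng = np.random.default_rng(123)
        r = arena.well_radius * np.sqrt(rng.random(10**6))
        occ = lk.zone_occupancy(radial_trajectory(r), arena)
        assert occ.pct_outer == pytest.approx(64.0, abs=0.2)


class TestDensityMap:
    def test_static_larva_single_bin(self, arena):
        traj = make_trajectory(np.full(20, 3.0), np.full(20, -2.0))
        dmap = lk.occupancy_density_map([traj], arena, n_bins=15)
        assert dmap.grid.max() == pytest.approx(1.0)
        assert np.count_nonzero(dmap.grid) == 1

    def test_total_mass_is_one(self, arena):
        rng = np.random.default_rng(2)
        trajs = [
            radial_trajectory(7.4 * np.sqrt(rng.random(500))) for _ in range(3)
        ]
        dmap = lk.occupancy_density_map(trajs, arena)
        assert dmap.grid.sum() == pytest.approx(1.0)

    def test_uniform_fill_proportional_to_bin_area(self, arena):
        """Area-uniform samples fill central (fully inside) bins uniformly."""
        from scipy import stats

        rng = np.random.default_rng(3)
        n = 200_000
        r = arena.well_radius * np.sqrt(rng.random(n))
        th = 2 * np.pi * rng.random(n)
        traj = make_trajectory(r * np.cos(th), r * np.sin(th))
        dmap = lk.occupancy_density_map([traj], arena, n_bins=10)
        counts = (dmap.grid * n)[3:7, 3:7].ravel()  # bins fully inside well
        assert stats.chisquare(counts).pvalue > 0.01

    def test_too_few_bins_rejected(self, arena):
        with pytest.raises(ValueError):
            lk.occupancy_density_map([radial_trajectory([1.0])], arena, n_bins=1)


class TestWallArrivalEvents:
    def test_never_near_wall_empty(self, arena):
        assert lk.wall_arrival_events(radial_trajectory(np.full(50, 3.0)), arena) == []

    def test_start_at_wall_counts_at_frame_zero(self, arena):
        events = lk.wall_arrival_events(radial_trajectory(np.full(50, 7.2)), arena)
        assert len(events) == 1 and events[0].frame == 0

    def test_sawtooth_counts_each_crossing(self, arena):
        """Five dips below 0.5 mm from the wall give five events."""
        one_cycle = np.concatenate([np.full(5, 6.0), np.full(5, 7.2)])
        r = np.tile(one_cycle, 5)
        events = lk.wall_arrival_events(radial_trajectory(r), arena)
        assert [e.frame for e in events] == [5, 15, 25, 35, 45]

    def test_censoring_flag(self, arena):
        # 30 s window at 30 Hz = 900 frames; a 100-frame recording censors
        events = lk.wall_arrival_events(radial_trajectory(np.full(100, 7.2)), arena)
        assert events[0].censored


def _event_trajectory(leave_frame, n_frames, frame_rate=30.0):
    """One wall arrival at frame 0; leaves the 1 mm band at `leave_frame`."""
    r = np.full(n_frames, 7.2)  # 0.3 mm from wall
    if leave_frame < n_frames:
        r[leave_frame:] = 5.0
    return radial_trajectory(r, frame_rate=frame_rate)


class TestWallStayCurve:
    def test_never_leaving_cohort_stays_at_one(self, arena):
        trajs = [radial_trajectory(np.full(931 * 1, 7.2)) for _ in range(3)]
        curve = lk.wall_stay_curve(trajs, arena)
        assert np.all(curve.p_stay == 1.0)

    def test_p_stay_starts_at_one(self, arena):
        curve = lk.wall_stay_curve([_event_trajectory(5, 931)], arena)
        assert curve.p_stay[0] == 1.0

    def test_exponential_departures_match_survival(self, arena):
        """500 events with exponential leave times (lambda = 0.2/s) follow
        exp(-0.2 t) within binomial error; sup distance < 0.05."""
        rng = np.random.default_rng(42)
        fr = 30.0
        leave = rng.exponential(1 / 0.2, size=500)
        trajs = [
            _event_trajectory(int(np.floor(t * fr)) + 1, 931, fr) for t in leave
        ]
        curve = lk.wall_stay_curve(trajs, arena)
        expected = np.exp(-0.2 * curve.times)
        assert np.max(np.abs(curve.p_stay - expected)) < 0.05
        for t_check in (1.0, 5.0, 15.0):
            j = int(t_check * fr)
            p = expected[j]
            se = np.sqrt(p * (1 - p) / 500)
            assert abs(curve.p_stay[j] - p) < 4 * se + 1e-9

    def test_instantaneous_allows_return(self, arena):
        r = np.full(931, 7.2)
        r[10:20] = 5.0  # brief excursion beyond 1 mm
        r[20:] = 6.8  # returns into the stay band without a new arrival
        traj = radial_trajectory(r)
        cont = lk.wall_stay_curve([traj], arena)
        inst = lk.wall_stay_curve([traj], arena, instantaneous=True)
        assert cont.p_stay[25] == 0.0
        assert inst.p_stay[25] == 1.0

    def test_comparison_p_values(self, arena):
        stay = [_event_trajectory(931, 931) for _ in range(30)]
        leave = [_event_trajectory(2, 931) for _ in range(30)]
        curve = lk.wall_stay_curve(stay, arena, compare=leave)
        assert curve.p_values[60] < 0.001  # all stayed vs all left by 2 s

    def test_no_events_rejected(self, arena):
        with pytest.raises(ValueError):
            lk.wall_stay_curve([radial_trajectory(np.full(50, 3.0))], arena)


class TestCrossingTrajectories:
    def test_outward_mover_reaches_wall_at_geometric_time(self, arena):
        """Constant outward radial motion: p_reach_wall steps to 1 at the
        frame where distance-to-wall first drops below 0.5 mm."""
        fr = 30.0
        speed = 3.0  # mm/s outward
        r = 4.0 + speed / fr * np.arange(931)
        r = np.minimum(r, 7.4)
        traj = radial_trajectory(r, frame_rate=fr)
        res = lk.crossing_trajectories([traj], arena)
        # crossing at r >= 4.5: frame 5; reach r > 7.0 at frame 31; delta 26
        reach = np.flatnonzero(res.p_reach_wall >= 1.0)
        assert reach[0] == 26
        assert np.all(res.p_reach_wall[: reach[0]] == 0.0)

    def test_immediate_return_never_reaches(self, arena):
        r = np.concatenate([np.full(10, 4.0), [4.6], np.full(920, 4.0)])
        res = lk.crossing_trajectories([radial_trajectory(r)], arena)
        assert np.nanmax(res.p_reach_wall) == 0.0

    def test_time_slices_normalized(self, arena):
        rng = np.random.default_rng(5)
        r = 4.0 + 3.0 * rng.random(931)
        res = lk.crossing_trajectories([radial_trajectory(r)], arena)
        sums = res.map.grid.sum(axis=1)
        observed = sums > 0
        assert np.allclose(sums[observed], 1.0)

    def test_no_crossings_rejected(self, arena):
        with pytest.raises(ValueError):
            lk.crossing_trajectories([radial_trajectory(np.full(50, 3.0))], arena)


class TestCenterToWallPaths:
    def test_straight_radial_path_length(self, arena):
        """A straight radial swim from just inside the center disc to the
        wall has length ~ (7.5 - 0.5) - 7.5 sqrt(0.05) = 5.32 mm."""
        r = 1.67 + 0.05 * np.arange(120)
        paths = lk.center_to_wall_paths(radial_trajectory(r), arena)
        assert len(paths) == 1
        expected = (7.5 - 0.5) - 7.5 * np.sqrt(0.05)
        assert paths[0].path_length == pytest.approx(expected, abs=0.1)
        assert paths[0].path_length >= paths[0].straight_distance - 1e-12

    def test_never_entering_disc_empty(self, arena):
        r = 3.0 + 4.0 * np.abs(np.sin(np.linspace(0, 10, 200)))
        paths = lk.center_to_wall_paths(radial_trajectory(np.clip(r, 2.0, 7.4)), arena)
        assert paths == []

    def test_path_at_least_straight_distance(self, arena):
        rng = np.random.default_rng(7)
        from larvakin.synthetic import SwimParams, generate_trajectory

        traj = generate_trajectory(SwimParams(duration=300, seed=11))
        for p in lk.center_to_wall_paths(traj, arena):
            assert p.path_length >= p.straight_distance - 1e-9

    def test_rotation_invariance(self, arena):
        from larvakin.synthetic import SwimParams, generate_trajectory

        traj = generate_trajectory(SwimParams(duration=300, seed=13))
        paths = lk.center_to_wall_paths(traj, arena)
        theta = 1.234
        rot = make_trajectory(
            traj.x * np.cos(theta) - traj.y * np.sin(theta),
            traj.x * np.sin(theta) + traj.y * np.cos(theta),
        )
        paths_rot = lk.center_to_wall_paths(rot, arena)
        assert len(paths) == len(paths_rot)
        for a, b in zip(paths, paths_rot):
            assert a.path_length == pytest.approx(b.path_length, rel=1e-9)
            assert (a.start_frame, a.end_frame) == (b.start_frame, b.end_frame)


class TestCohortPhenotypes:
    def test_wall_affine_cohort_has_higher_outer_occupancy(self, arena):
        from larvakin.synthetic import generate_trajectory, mutant_like, wildtype_like

        wt = [
            lk.zone_occupancy(generate_trajectory(wildtype_like(duration=120, seed=s))).pct_outer
            for s in range(8)
        ]
        mu = [
            lk.zone_occupancy(generate_trajectory(mutant_like(duration=120, seed=50 + s))).pct_outer
            for s in range(8)
        ]
        assert np.median(wt) > np.median(mu)
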