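"""Place preference and wall-interaction scoring in a circular well.

Thigmotaxis — the preference for swimming along the arena wall — is scored
from well-centered trajectories: time share in an outer ring vs. an inner
disc, pooled occupancy density maps, the probability of remaining next to
the wall after arriving there, distance-from-edge distributions after
inner-to-outer crossings, and the length of paths from the well center to
the wall (a measure independent of activity and velocity).

Default geometry: a 15-mm-diameter well (radius 7.5 mm) split at radius
4.5 mm, so the inner disc covers 36% of the area and the outer ring 64%;
"at the wall edge" means within 0.5 mm of the wall, "next to the wall"
within 1 mm; the center disc for path extraction covers 5% of the area;
wall events are followed for a 30 s window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .kinematics import Trajectory

__all__ = [
    "ArenaGeometry",
    "OccupancyResult",
    "DensityMap",
    "WallArrivalEvent",
    "WallStayCurve",
    "CrossingAnalysis",
    "CenterToWallPath",
    "zone_occupancy",
    "occupancy_density_map",
    "wall_arrival_events",
    "wall_stay_curve",
    "crossing_trajectories",
    "center_to_wall_paths",
]


@dataclass(frozen=True)
class ArenaGeometry:
    """Well radius and the zone/threshold radii used by all scores.

    All lengths in mm; ``window`` in seconds.
    """

    well_radius: float = 7.5
    inner_radius: float = 4.5
    edge_reach: float = 0.5
    edge_stay: float = 1.0
    center_disc_area_fraction: float = 0.05
    window: float = 30.0

    def __post_init__(self) -> None:
        if not (0 < self.inner_radius < self.well_radius):
            raise ValueError("require 0 < inner_radius < well_radius")
        if not (0 < self.edge_reach <= self.edge_stay < self.well_radius):
            raise ValueError("require 0 < edge_reach <= edge_stay < well_radius")
        if not (0 < self.center_disc_area_fraction < 1):
            raise ValueError("center_disc_area_fraction must be in (0, 1)")
        if self.window <= 0:
            raise ValueError("window must be positive")

    @property
    def inner_area_fraction(self) -> float:
        return (self.inner_radius / self.well_radius) ** 2

    @property
    def center_disc_radius(self) -> float:
        return self.well_radius * np.sqrt(self.center_disc_area_fraction)


@dataclass
class OccupancyResult:
    pct_outer: float
    pct_inner: float
    random_outer_pct: float  # area-derived chance level


@dataclass
class DensityMap:
    """Normalized occupancy grid.

    ``kind == "occupancy"``: 2-D spatial histogram over the well, total
    mass 1.  ``kind == "time_distance"``: rows are time steps since a
    conditioning event, columns distance-from-edge bins; each row (time
    slice with any observed event) sums to 1.
    """

    grid: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    n_larvae: int
    kind: str = "occupancy"


@dataclass(frozen=True)
class WallArrivalEvent:
    """A crossing into the edge-reach band, observed for up to ``window`` s."""

    traj_index: int
    frame: int
    censored: bool  # observation window truncated by end of recording


@dataclass
class WallStayCurve:
    """P(still next to the wall) as a function of time since arrival.

    ``p_stay[0] == 1`` by construction.  ``n_events[j]`` is the number of
    events still contributing (censored events drop out of the denominator
    once their recording ends).  ``p_values`` is per-timepoint two-proportion
    test vs. a comparison cohort, NaN when no comparison was given.
    """

    times: np.ndarray
    p_stay: np.ndarray
    n_events: np.ndarray
    p_values: np.ndarray = field(default=None)  # type: ignore[assignment]


@dataclass
class CrossingAnalysis:
    """Distance-from-edge evolution after inner-to-outer crossings."""

    map: DensityMap
    times: np.ndarray
    p_reach_wall: np.ndarray  # cumulative fraction having touched the edge band


@dataclass
class CenterToWallPath:
    """One swim from the center disc to the wall-edge band."""

    start_frame: int
    end_frame: int
    path_length: float  # mm, summed step lengths
    straight_distance: float  # mm, start-to-end chord
    duration: float  # s
    starts_at_recording_edge: bool = False


# ---------------------------------------------------------------------------
# Zone occupancy
# ---------------------------------------------------------------------------

def zone_occupancy(traj: Trajectory, arena: ArenaGeometry = ArenaGeometry()) -> OccupancyResult:
    """Percentage of (non-missing) time in the outer ring vs. inner disc.

    A frame is inner iff r < inner_radius (the boundary circle itself counts
    as outer).  ``random_outer_pct`` is the area fraction a place-indifferent
    swimmer would show.
    """
    ok = ~traj.missing_mask()
    if not np.any(ok):
        raise ValueError("trajectory has no usable samples")
    r = traj.radius()[ok]
    inner = np.mean(r < arena.inner_radius)
    random_outer = (1.0 - arena.inner_area_fraction) * 100.0
    return OccupancyResult(
        pct_outer=float((1.0 - inner) * 100.0),
        pct_inner=float(inner * 100.0),
        random_outer_pct=float(random_outer),
    )


def occupancy_density_map(
    trajs: list[Trajectory],
    arena: ArenaGeometry = ArenaGeometry(),
    n_bins: int = 30,
) -> DensityMap:
    """Pooled 2-D position histogram over the well, normalized to sum 1."""
    if not trajs:
        raise ValueError("need at least one trajectory")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    R = arena.well_radius
    edges = np.linspace(-R, R, n_bins + 1)
    grid = np.zeros((n_bins, n_bins))
    for traj in trajs:
        ok = ~traj.missing_mask()
        h, _, _ = np.histogram2d(traj.x[ok], traj.y[ok], bins=(edges, edges))
        grid += h
    total = grid.sum()
    if total == 0:
        raise ValueError("no usable samples in any trajectory")
    return DensityMap(grid / total, edges, edges, n_larvae=len(trajs))


# ---------------------------------------------------------------------------
# Wall events and stay curves
# ---------------------------------------------------------------------------

def _distance_to_wall(traj: Trajectory, arena: ArenaGeometry) -> np.ndarray:
    return arena.well_radius - traj.radius()


def wall_arrival_events(
    traj: Trajectory,
    arena: ArenaGeometry = ArenaGeometry(),
    traj_index: int = 0,
) -> list[WallArrivalEvent]:
    """Frames where the larva crosses into the edge-reach band (< 0.5 mm).

    An arrival is a downward crossing of ``edge_reach`` of the distance to
    the wall; a recording that starts inside the band counts as an arrival
    at frame 0.  Events whose follow-up window runs past the recording end
    are marked censored.
    """
    d = _distance_to_wall(traj, arena)
    inside = d < arena.edge_reach
    window_frames = int(round(arena.window * traj.frame_rate))
    events = []
    prev = False
    for i, now in enumerate(inside):
        if now and not prev:
            censored = i + window_frames >= len(traj)
            events.append(WallArrivalEvent(traj_index, i, censored))
        prev = now
    return events


def wall_stay_curve(
    trajs: list[Trajectory],
    arena: ArenaGeometry = ArenaGeometry(),
    instantaneous: bool = False,
    compare: list[Trajectory] | None = None,
) -> WallStayCurve:
    """Probability of remaining next to the wall (< edge_stay) after arrival.

    By default "remaining" means continuous residence: an event survives to
    time t only if its distance to the wall stayed below ``edge_stay`` at
    every frame up to t.  With ``instantaneous=True`` the curve is instead
    the fraction of events whose distance is below ``edge_stay`` at exactly
    t, regardless of excursions in between.

    When ``compare`` is given, per-timepoint p-values from a two-proportion
    z-test (stayed vs. departed) against the comparison cohort are included.
    """
    stay, obs, fr = _collect_stay_times(trajs, arena, instantaneous)
    if stay.shape[1] == 0:
        raise ValueError("no wall-arrival events in cohort")
    window_frames = stay.shape[0] - 1
    times = np.arange(window_frames + 1) / fr

    def curve(stay_m, obs_m):
        n_at = obs_m.sum(axis=1)
        k_at = np.where(obs_m, stay_m, False).sum(axis=1)
        with np.errstate(invalid="ignore"):
            p = np.where(n_at > 0, k_at / np.maximum(n_at, 1), np.nan)
        return p, k_at, n_at

    p, k_at, n_at = curve(stay, obs)
    p_values = np.full(times.shape, np.nan)
    if compare is not None:
        stay_c, obs_c, _ = _collect_stay_times(compare, arena, instantaneous)
        if stay_c.shape[1] == 0:
            raise ValueError("no wall-arrival events in comparison cohort")
        _, k_c, n_c = curve(stay_c, obs_c)
        for j in range(times.size):
            p_values[j] = _two_proportion_p(k_at[j], n_at[j], k_c[j], n_c[j])
    return WallStayCurve(times=times, p_stay=p, n_events=n_at, p_values=p_values)


def _collect_stay_times(trajs, arena, instantaneous):
    """Boolean (window+1, n_events) matrices: still-at-wall and observed."""
    window_frames = None
    cols_stay, cols_obs = [], []
    fr = trajs[0].frame_rate
    for idx, traj in enumerate(trajs):
        if traj.frame_rate != fr:
            raise ValueError("cohort trajectories must share a frame rate")
        if window_frames is None:
            window_frames = int(round(arena.window * fr))
        d = _distance_to_wall(traj, arena)
        for ev in wall_arrival_events(traj, arena, traj_index=idx):
            seg = d[ev.frame : ev.frame + window_frames + 1]
            at_wall = seg < arena.edge_stay
            at_wall[0] = True  # p_stay(0) = 1 by construction
            if not instantaneous:
                at_wall = np.logical_and.accumulate(at_wall)
            stay = np.zeros(window_frames + 1, dtype=bool)
            obs = np.zeros(window_frames + 1, dtype=bool)
            stay[: at_wall.size] = at_wall
            obs[: at_wall.size] = True
            cols_stay.append(stay)
            cols_obs.append(obs)
    if not cols_stay:
        return (
            np.zeros((int(window_frames or 0) + 1, 0), dtype=bool),
            np.zeros((int(window_frames or 0) + 1, 0), dtype=bool),
            fr,
        )
    return np.column_stack(cols_stay), np.column_stack(cols_obs), fr


def _two_proportion_p(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided pooled two-proportion z-test p-value."""
    if n1 == 0 or n2 == 0:
        return np.nan
    p_pool = (k1 + k2) / (n1 + n2)
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    if se == 0:
        return 1.0
    z = (k1 / n1 - k2 / n2) / se
    return float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Crossing trajectories and wall-arrival maps
# ---------------------------------------------------------------------------

def crossing_trajectories(
    trajs: list[Trajectory],
    arena: ArenaGeometry = ArenaGeometry(),
    bin_width: float = 0.25,
) -> CrossingAnalysis:
    """Distance-from-edge distribution after inner-to-outer crossings.

    Each crossing of the inner-zone circle from inside to outside defines
    t = 0; for the following ``window`` the per-timepoint distribution of
    distance from the wall is histogrammed (each time slice normalized to
    the events observed at that time).  ``p_reach_wall[t]`` is the
    cumulative fraction of observed crossings that have entered the
    edge-reach band by t.
    """
    fr = trajs[0].frame_rate
    window_frames = int(round(arena.window * fr))
    n_dist_bins = int(np.ceil(arena.well_radius / bin_width))
    dist_edges = np.arange(n_dist_bins + 1) * bin_width
    counts = np.zeros((window_frames + 1, n_dist_bins))
    reached = np.zeros(window_frames + 1)
    observed = np.zeros(window_frames + 1)
    n_events = 0
    for traj in trajs:
        if traj.frame_rate != fr:
            raise ValueError("cohort trajectories must share a frame rate")
        r = traj.radius()
        d = _distance_to_wall(traj, arena)
        outside = r >= arena.inner_radius
        crossings = np.flatnonzero(outside[1:] & ~outside[:-1]) + 1
        for c in crossings:
            n_events += 1
            seg = d[c : c + window_frames + 1]
            idx = np.clip((seg / bin_width).astype(int), 0, n_dist_bins - 1)
            t = np.arange(seg.size)
            counts[t, idx] += 1
            observed[: seg.size] += 1
            hit = np.flatnonzero(seg < arena.edge_reach)
            if hit.size:
                reached[hit[0] :][: seg.size - hit[0]] += 1
    if n_events == 0:
        raise ValueError("no inner-to-outer crossings in cohort")
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        grid = np.where(row_sums > 0, counts / np.maximum(row_sums, 1), 0.0)
    times = np.arange(window_frames + 1) / fr
    with np.errstate(invalid="ignore"):
        p_reach = np.where(observed > 0, reached / np.maximum(observed, 1), np.nan)
    dmap = DensityMap(grid, times, dist_edges, n_larvae=len(trajs), kind="time_distance")
    return CrossingAnalysis(map=dmap, times=times, p_reach_wall=p_reach)


# ---------------------------------------------------------------------------
# Center-to-wall paths
# ---------------------------------------------------------------------------

def center_to_wall_paths(
    traj: Trajectory,
    arena: ArenaGeometry = ArenaGeometry(),
) -> list[CenterToWallPath]:
    """Paths from the center disc (5% of well area) to the wall-edge band.

    A path starts at the last frame inside the center disc before a wall
    contact and ends at the first subsequent frame within ``edge_reach`` of
    the wall, with no intermediate re-entry into the disc (guaranteed by
    the last-exit convention).  A recording that starts inside the disc can
    seed a path at frame 0 (flagged).  Paths containing missing samples are
    skipped.
    """
    r = traj.radius()
    d = _distance_to_wall(traj, arena)
    r_c = arena.center_disc_radius
    in_disc = r < r_c
    at_wall = d < arena.edge_reach
    missing = traj.missing_mask()

    paths: list[CenterToWallPath] = []
    last_center: int | None = None
    for i in range(len(traj)):
        if in_disc[i] and not missing[i]:
            last_center = i
        elif at_wall[i] and last_center is not None:
            s, e = last_center, i
            span_missing = np.any(missing[s : e + 1])
            if not span_missing and e > s:
                steps = np.hypot(
                    np.diff(traj.x[s : e + 1]), np.diff(traj.y[s : e + 1])
                )
                straight = float(
                    np.hypot(traj.x[e] - traj.x[s], traj.y[e] - traj.y[s])
                )
                paths.append(
                    CenterToWallPath(
                        start_frame=s,
                        end_frame=e,
                        path_length=float(steps.sum()),
                        straight_distance=straight,
                        duration=(e - s) / traj.frame_rate,
                        starts_at_recording_edge=(s == 0 and in_disc[0]),
                    )
                )
            last_center = None  # next path requires a fresh disc entry
    return paths
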