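"""Open-field locomotion and spatial-occupancy metrics.

A 10-minute session in a square arena (study geometry: 1.83 m x 1.83 m with
an entry door) is summarized from a pose track by: total distance traveled by
a chosen body part, a normalized occupancy heatmap, and dwell in the door
zone — the band of configurable depth (0.30 m in the study) along the door
wall, where pigs concentrate their time.  Escape attempts are manually
annotated and summarized from an event log, not detected from coordinates.

Arena coordinates: origin at the door-wall/left-wall corner, x along the door
wall, y away from it (y-up).  Image pixels are y-down; the calibration in
:class:`ArenaGeometry` performs the flip once, and all geometry downstream is
in arena meters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import EventLog, PoseTrack, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ArenaGeometry:
    """Square arena with a door zone, plus the pixel calibration.

    ``origin_px`` is the pixel position of the door-wall/left-wall corner;
    ``y_down`` says whether pixel y grows downward (image convention).
    """

    side_length: float = 1.83  # m
    door_wall: str = "S"  # the wall holding the door; y=0 in arena coords
    door_center: float = 0.915  # m along the door wall
    door_zone_depth: float = 0.30  # m
    px_per_meter: float = 300.0
    origin_px: tuple[float, float] = (0.0, 549.0)
    y_down: bool = True

    def __post_init__(self) -> None:
        if not self.side_length > 0:
            raise ValidationError("side_length must be > 0")
        if not 0 <= self.door_center <= self.side_length:
            raise ValidationError("door_center must lie on the door wall")
        if not self.px_per_meter > 0:
            raise ValidationError("px_per_meter must be > 0")
        if self.door_wall not in "NESW":
            raise ValidationError("door_wall must be one of N/E/S/W")

    @classmethod
    def from_corners(
        cls, door_left_px, door_right_px, side_length: float = 1.83, **kwargs
    ) -> "ArenaGeometry":
        """Calibrate px/m from the two door-wall corner pixels (axis-aligned image)."""
        d = float(np.hypot(door_right_px[0] - door_left_px[0], door_right_px[1] - door_left_px[1]))
        return cls(
            side_length=side_length,
            px_per_meter=d / side_length,
            origin_px=(float(door_left_px[0]), float(door_left_px[1])),
            **kwargs,
        )

    def to_arena(self, xy_px: np.ndarray) -> np.ndarray:
        """Pixel coordinates -> arena meters (y-up, origin at door-left corner)."""
        xy_px = np.asarray(xy_px, float)
        x = (xy_px[..., 0] - self.origin_px[0]) / self.px_per_meter
        dy = (xy_px[..., 1] - self.origin_px[1]) / self.px_per_meter
        y = -dy if self.y_down else dy
        return np.stack([x, y], axis=-1)

    def to_px(self, xy_m: np.ndarray) -> np.ndarray:
        xy_m = np.asarray(xy_m, float)
        px = xy_m[..., 0] * self.px_per_meter + self.origin_px[0]
        dy = xy_m[..., 1] * self.px_per_meter
        py = self.origin_px[1] - dy if self.y_down else self.origin_px[1] + dy
        return np.stack([px, py], axis=-1)

    def in_door_zone(self, xy_m: np.ndarray) -> np.ndarray:
        """Boolean mask: inside the door band (depth ``door_zone_depth`` at y=0)."""
        return np.asarray(xy_m, float)[..., 1] < self.door_zone_depth


@dataclass
class OccupancyMap:
    """Normalized 2D histogram of position; ``grid[iy, ix]``, row 0 at the door wall."""

    grid: np.ndarray
    cell_size: float  # m
    n_clamped: int = 0

    @property
    def n_bins(self) -> int:
        return self.grid.shape[0]


def filter_confidence(track: PoseTrack, threshold: float = 0.9, max_gap: int = 10) -> PoseTrack:
    """Mask low-confidence points and bridge short gaps.

    Points with likelihood below ``threshold`` become missing; interior
    missing runs of length <= ``max_gap`` frames are linearly interpolated,
    longer runs stay missing.  Total: never raises.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    data = track.data.copy()
    for bp in track.bodyparts:
        lik = track.likelihood(bp)
        xy = data[bp][["x", "y"]].to_numpy(float)
        if lik is not None:
            low = ~np.isnan(lik) & (lik < threshold)
            xy[low] = np.nan
        for col in range(2):
            xy[:, col] = _bridge_gaps(xy[:, col], max_gap)
        data[(bp, "x")] = xy[:, 0]
        data[(bp, "y")] = xy[:, 1]
    return PoseTrack(data, track.frame_rate, track.subject_id, track.session_time)


def _bridge_gaps(v: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly interpolate interior NaN runs of length <= max_gap."""
    v = v.copy()
    isnan = np.isnan(v)
    if not isnan.any() or isnan.all():
        return v
    idx = np.arange(len(v))
    # run starts/ends of NaN stretches
    d = np.diff(isnan.astype(int))
    starts = list(idx[1:][d == 1])
    ends = list(idx[1:][d == -1])  # first valid index after each run
    if isnan[0]:
        starts.insert(0, 0)
    if isnan[-1]:
        ends.append(len(v))
    for s, e in zip(starts, ends):
        if s == 0 or e == len(v):
            continue  # edge runs have no anchor on one side
        if e - s <= max_gap:
            v[s:e] = np.interp(idx[s:e], [s - 1, e], [v[s - 1], v[e]])
    return v


def _valid_arena_xy(track: PoseTrack, bodypart: str, arena: ArenaGeometry) -> np.ndarray:
    xy = arena.to_arena(track.xy(bodypart))
    return xy[~np.isnan(xy).any(axis=1)]


def path_length(track: PoseTrack, bodypart: str, arena: ArenaGeometry) -> float:
    """Total distance traveled by one body part, in meters.

    Sum of Euclidean steps between consecutive valid frames; a missing run
    contributes the straight-line distance across it.
    """
    xy = _valid_arena_xy(track, bodypart, arena)
    if len(xy) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(xy, axis=0), axis=1).sum())


def occupancy_map(
    track: PoseTrack, bodypart: str, arena: ArenaGeometry, n_bins: int = 61
) -> OccupancyMap:
    """Normalized occupancy histogram over the arena (total mass 1).

    Out-of-arena points are clamped to the boundary cells and counted.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    xy = _valid_arena_xy(track, bodypart, arena)
    if len(xy) == 0:
        raise ValidationError("no valid frames to histogram")
    L = arena.side_length
    outside = ((xy < 0) | (xy > L)).any(axis=1)
    n_clamped = int(outside.sum())
    if n_clamped:
        logger.info("clamped %d out-of-arena points to the boundary", n_clamped)
    xy = np.clip(xy, 0.0, np.nextafter(L, 0.0))
    edges = np.linspace(0.0, L, n_bins + 1)
    grid, _, _ = np.histogram2d(xy[:, 1], xy[:, 0], bins=[edges, edges])
    grid /= grid.sum()
    return OccupancyMap(grid=grid, cell_size=L / n_bins, n_clamped=n_clamped)


def zone_dwell(track: PoseTrack, bodypart: str, arena: ArenaGeometry) -> tuple[float, float]:
    """(fraction, seconds) of valid session time spent in the door zone."""
    xy = _valid_arena_xy(track, bodypart, arena)
    if len(xy) == 0:
        return float("nan"), float("nan")
    frac = float(arena.in_door_zone(xy).mean())
    return frac, frac * track.duration


def escape_summary(log: EventLog) -> tuple[int, float]:
    """(count, cumulative seconds) of annotated escape bouts."""
    df = log.data[log.data["label"] == "escape"]
    if df["end"].isna().any():
        raise ValidationError("escape events must be intervals (end required)")
    durations = (df["end"] - df["start"]).to_numpy(float)
    return len(df), float(durations.sum())
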