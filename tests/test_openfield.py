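"""Locomotor and spatial metrics: analytic tracks, generator truth, invariances."""

import numpy as np
import pandas as pd
import pytest

from pigpheno import openfield as of
from pigpheno import synthetic
from pigpheno.io_formats import EventLog, PoseTrack, ValidationError


def make_track(xy_px, frame_rate=30.0, likelihood=None):
    xy_px = np.asarray(xy_px, float)
    cols = {("bp", "x"): xy_px[:, 0], ("bp", "y"): xy_px[:, 1]}
    if likelihood is not None:
        cols[("bp", "likelihood")] = np.asarray(likelihood, float)
    df = pd.DataFrame(cols)
    df.columns = df.columns.set_names(["bodypart", "coord"])
    return PoseTrack(df, frame_rate)


UNIT_ARENA = of.ArenaGeometry(
    side_length=2.0, door_center=1.0, px_per_meter=100.0, origin_px=(0.0, 200.0)
)


class TestFilterConfidence:
    def test_full_confidence_is_identity(self):
        track = make_track([[0, 0], [10, 10], [20, 20]], likelihood=[1, 1, 1])
        out = of.filter_confidence(track, 0.9, 10)
        assert np.array_equal(out.xy("bp"), track.xy("bp"))

    def test_single_low_frame_interpolated(self):
        track = make_track([[0, 0], [99, 99], [200, 0]], likelihood=[1, 0.1, 1])
        out = of.filter_confidence(track, 0.9, 10)
        assert out.xy("bp")[1].tolist() == [100.0, 0.0]

    def test_gap_longer_than_max_gap_stays_missing(self):
        n = 8
        lik = np.ones(n)
        lik[2:6] = 0.0  # 4-frame gap
        xy = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
        out = of.filter_confidence(make_track(xy, likelihood=lik), 0.9, max_gap=3)
        assert np.isnan(out.xy("bp")[2:6]).all()
        out2 = of.filter_confidence(make_track(xy, likelihood=lik), 0.9, max_gap=4)
        assert not np.isnan(out2.xy("bp")).any()


class TestPathLength:
    def test_stationary_track_is_zero(self):
        track = make_track(np.tile([50.0, 50.0], (100, 1)))
        assert of.path_length(track, "bp", UNIT_ARENA) == 0.0

    def test_square_perimeter_is_exact(self):
        # 1 m x 1 m square at 100 px/m, sampled at its corners and closed
        corners_px = np.array([[0, 200], [100, 200], [100, 100], [0, 100], [0, 200]], float)
        track = make_track(corners_px)
        assert of.path_length(track, "bp", UNIT_ARENA) == pytest.approx(4.0, abs=1e-12)

    def test_matches_generator_truth(self):
        track, gt = synthetic.simulate_openfield(seed=2, duration=60.0)
        got = of.path_length(track, "head_back", of.ArenaGeometry())
        assert got == pytest.approx(gt.truth["path_length_m"], rel=1e-6)

    def test_missing_run_contributes_straight_line(self):
        xy = np.array([[0, 200], [np.nan, np.nan], [100, 200]], float)
        track = make_track(xy)
        # straight line across the gap: 1 m, not 0
        assert of.path_length(track, "bp", UNIT_ARENA) == pytest.approx(1.0)

    def test_unknown_bodypart_raises(self):
        track = make_track([[0, 0], [1, 1]])
        with pytest.raises(KeyError):
            of.path_length(track, "tail", UNIT_ARENA)

    def test_at_least_straight_line_displacement_and_scaling(self):
        track, _ = synthetic.simulate_openfield(seed=5, duration=30.0)
        arena = of.ArenaGeometry()
        xy = arena.to_arena(track.xy("head_back"))
        straight = float(np.linalg.norm(xy[-1] - xy[0]))
        assert of.path_length(track, "head_back", arena) >= straight
        doubled = of.ArenaGeometry(px_per_meter=arena.px_per_meter * 2)
        assert of.path_length(track, "head_back", doubled) == pytest.approx(
            of.path_length(track, "head_back", arena) / 2
        )

    def test_invariant_under_pixel_rotation(self):
        track, _ = synthetic.simulate_openfield(seed=6, duration=20.0)
        arena = of.ArenaGeometry()
        base = of.path_length(track, "head_back", arena)
        theta = 0.3
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        rotated = make_track(track.xy("head_back") @ R.T, frame_rate=track.frame_rate)
        assert of.path_length(rotated, "bp", arena) == pytest.approx(base, rel=1e-9)


class TestOccupancy:
    def test_all_frames_at_center_single_cell(self):
        arena = UNIT_ARENA
        center_px = arena.to_px(np.array([1.0, 1.0]))
        track = make_track(np.tile(center_px, (50, 1)))
        occ = of.occupancy_map(track, "bp", arena, n_bins=5)
        assert occ.grid[2, 2] == pytest.approx(1.0)
        assert occ.grid.sum() == pytest.approx(1.0, abs=1e-9)

    def test_mass_conserved_and_reflection_equivariant(self):
        track, _ = synthetic.simulate_openfield(seed=7, duration=30.0)
        arena = of.ArenaGeometry()
        occ = of.occupancy_map(track, "bp" if False else "head_back", arena, n_bins=9)
        assert occ.grid.sum() == pytest.approx(1.0, abs=1e-9)
        # reflect the track about the arena's vertical midline
        xy = arena.to_arena(track.xy("head_back"))
        xy[:, 0] = arena.side_length - xy[:, 0]
        mirrored = make_track(arena.to_px(xy), frame_rate=track.frame_rate)
        occ_m = of.occupancy_map(mirrored, "bp", arena, n_bins=9)
        assert np.allclose(occ_m.grid, occ.grid[:, ::-1])

    def test_uniformity_improves_with_more_frames(self):
        arena = of.ArenaGeometry()
        devs = []
        for duration in (40.0, 640.0):
            track, _ = synthetic.simulate_openfield(
                seed=8, duration=duration, step_scale=0.4, frame_rate=30.0
            )
            occ = of.occupancy_map(track, "head_back", arena, n_bins=4)
            devs.append(np.abs(occ.grid - 1.0 / 16).max())
        assert devs[1] < devs[0]

    def test_door_biased_track_peaks_in_door_zone(self):
        arena = of.ArenaGeometry()
        track, _ = synthetic.simulate_openfield(seed=9, door_bias=0.6)
        occ = of.occupancy_map(track, "head_back", arena)
        iy, _ = np.unravel_index(occ.grid.argmax(), occ.grid.shape)
        assert (iy + 0.5) * occ.cell_size < arena.door_zone_depth

    def test_all_missing_raises(self):
        track = make_track(np.full((5, 2), np.nan))
        with pytest.raises(ValidationError):
            of.occupancy_map(track, "bp", UNIT_ARENA)


class TestZoneDwell:
    def test_track_in_door_band_is_one(self):
        arena = UNIT_ARENA
        xy = arena.to_px(np.column_stack([np.linspace(0.1, 1.9, 60), np.full(60, 0.1)]))
        frac, secs = of.zone_dwell(make_track(xy), "bp", arena)
        assert frac == 1.0
        assert secs == pytest.approx(2.0)  # 60 frames at 30 fps

    def test_track_on_far_wall_is_zero(self):
        arena = UNIT_ARENA
        xy = arena.to_px(np.column_stack([np.linspace(0.1, 1.9, 60), np.full(60, 1.9)]))
        frac, _ = of.zone_dwell(make_track(xy), "bp", arena)
        assert frac == 0.0

    def test_programmed_dwell_recovered(self):
        arena = of.ArenaGeometry()
        track, gt = synthetic.simulate_openfield(seed=10, door_bias=0.6, duration=300.0)
        frac, _ = of.zone_dwell(track, "head_back", arena)
        assert frac == pytest.approx(gt.truth["door_zone_fraction"], abs=1e-12)
        assert frac == pytest.approx(0.6, abs=0.12)  # single-run switching-walk tolerance


class TestEscapeSummary:
    def test_empty_log(self):
        log = EventLog(pd.DataFrame({"session_id": [], "label": [], "start": [], "end": []}))
        assert of.escape_summary(log) == (0, 0.0)

    def test_two_intervals(self):
        log = EventLog(
            pd.DataFrame(
                {"session_id": ["s", "s"], "label": ["escape", "escape"], "start": [0.0, 10.0], "end": [5.0, 12.0]}
            )
        )
        assert of.escape_summary(log) == (2, 7.0)

    def test_instant_event_rejected(self):
        log = EventLog(
            pd.DataFrame({"session_id": ["s"], "label": ["escape"], "start": [1.0], "end": [np.nan]})
        )
        with pytest.raises(ValidationError):
            of.escape_summary(log)

    def test_matches_generator_truth(self):
        log, gt = synthetic.simulate_escapes(n_bouts=15, seed=3)
        count, cum = of.escape_summary(log)
        assert count == gt.truth["count"] == 15
        assert cum == pytest.approx(gt.truth["cumulative_s"], rel=1e-12)
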