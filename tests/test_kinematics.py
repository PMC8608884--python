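"""Pod frames, angle decomposition, touchdown detection and gait segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from pigpheno import kinematics as kin
from pigpheno import synthetic


def random_rotation(rng):
    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


class TestPodFrame:
    def test_unit_triangle(self):
        f = kin.pod_frame([0, 0, 0], [1, 0, 0], [0, 1, 0], front=1)
        assert np.allclose(f.origin, [1 / 3, 1 / 3, 0])
        assert np.allclose(f.basis[:, 2], [0, 0, 1])

    def test_translation_invariance(self):
        pts = np.array([[0.1, 0.0, 0.0], [-0.05, 0.08, 0.0], [-0.05, -0.08, 0.0]])
        shift = np.array([3.0, -2.0, 7.0])
        a = kin.pod_frame(*pts)
        b = kin.pod_frame(*(pts + shift))
        assert np.allclose(a.basis, b.basis)
        assert np.allclose(b.origin, a.origin + shift)

    def test_orthonormal_right_handed_vs_gram_schmidt(self):
        """Random triads: basis matches an independent Gram-Schmidt construction."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            pts = rng.normal(size=(3, 3))
            area = np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[0])) / 2
            if area < 1e-6:
                continue
            f = kin.pod_frame(*pts)
            B = f.basis
            assert np.allclose(B.T @ B, np.eye(3), atol=1e-9)
            assert np.linalg.det(B) == pytest.approx(1.0, abs=1e-9)
            # oracle: orthonormalize (anterior, any-in-plane) by Gram-Schmidt,
            # normal from the cross product
            centroid = pts.mean(axis=0)
            n = np.cross(pts[1] - pts[0], pts[2] - pts[0])
            n = n / np.linalg.norm(n)
            if n @ np.array([0.0, 0.0, 1.0]) < 0:
                n = -n
            d = pts[0] - centroid
            a = d - (d @ n) * n
            a = a / np.linalg.norm(a)
            assert np.allclose(B[:, 0], a, atol=1e-9)
            assert np.allclose(B[:, 2], n, atol=1e-9)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(1)
        pts = np.array([[0.12, 0.0, 0.01], [-0.06, 0.09, -0.01], [-0.06, -0.09, 0.0]])
        base = kin.pod_frame(*pts)
        for _ in range(20):
            R = random_rotation(rng)
            rotated = kin.pod_frame(*(pts @ R.T), prev_normal=R @ base.basis[:, 2])
            assert np.allclose(rotated.basis, R @ base.basis, atol=1e-9)

    def test_collinear_markers_rejected(self):
        with pytest.raises(kin.DegeneratePodError):
            kin.pod_frame([0, 0, 0], [1, 0, 0], [2, 0, 0])


def bases_for(rotations):
    bases = np.stack([r for r in rotations])
    return bases, np.ones(len(bases), dtype=bool)


class TestPodAngles:
    def test_identity_is_zero(self):
        bases, valid = bases_for([np.eye(3)] * 5)
        ang = kin.pod_angles(bases, valid, 100.0)
        assert np.allclose([ang.yaw, ang.pitch, ang.roll], 0.0)

    def test_pure_yaw(self):
        R = Rotation.from_euler("Z", 30, degrees=True).as_matrix()
        bases, valid = bases_for([np.eye(3), R])
        ang = kin.pod_angles(bases, valid, 100.0)
        assert ang.yaw[1] == pytest.approx(30.0, abs=1e-9)
        assert ang.pitch[1] == pytest.approx(0.0, abs=1e-9)
        assert ang.roll[1] == pytest.approx(0.0, abs=1e-9)

    def test_round_trip_of_known_rotation(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            ypr = rng.uniform([-170, -80, -170], [170, 80, 170])
            R = Rotation.from_euler("ZYX", ypr, degrees=True).as_matrix()
            ang = kin.pod_angles(*bases_for([np.eye(3), R]), 100.0)
            got = np.array([ang.yaw[1], ang.pitch[1], ang.roll[1]])
            assert np.allclose(got, ypr, atol=1e-6)

    def test_gimbal_flagged(self):
        R = Rotation.from_euler("ZYX", [10, 88, 5], degrees=True).as_matrix()
        ang = kin.pod_angles(*bases_for([np.eye(3), R]), 100.0)
        assert ang.gimbal[1]


class TestAngleRange:
    def test_constant_channel_zero(self):
        bases, valid = bases_for([np.eye(3)] * 10)
        ang = kin.pod_angles(bases, valid, 100.0)
        assert kin.angle_range(ang, "yaw") == 0.0

    def test_sinusoid_amplitude_six_gives_twelve(self):
        t = np.arange(400) / 100.0
        yaw = 6 * np.sin(2 * np.pi * t)
        rots = Rotation.from_euler(
            "ZYX", np.column_stack([yaw, np.zeros_like(yaw), np.zeros_like(yaw)]), degrees=True
        ).as_matrix()
        ang = kin.pod_angles(*bases_for(rots), 100.0)
        assert kin.angle_range(ang, "yaw") == pytest.approx(12.0, abs=1e-9)

    def test_time_reversal_and_reference_offset_invariance(self):
        series, _ = synthetic.simulate_gait(duration=2.0, seed=3)
        _, bases, valid = kin.pod_frames(series, "head")
        fwd = kin.pod_angles(bases, valid, 100.0)
        rev = kin.pod_angles(bases[::-1], valid[::-1], 100.0, reference=bases[0])
        off = kin.pod_angles(
            bases, valid, 100.0,
            reference=bases[0] @ Rotation.from_euler("Z", 25, degrees=True).as_matrix(),
        )
        for ch in ("yaw", "pitch", "roll"):
            assert kin.angle_range(rev, ch) == pytest.approx(kin.angle_range(fwd, ch), abs=1e-9)
            assert kin.angle_range(off, ch) == pytest.approx(kin.angle_range(fwd, ch), abs=1e-6)


class TestMeanVelocity:
    def test_forward_advance(self):
        t = np.arange(101) / 100.0
        origins = np.column_stack([1.93 * t, np.zeros_like(t), np.zeros_like(t)])
        vel, speed = kin.mean_velocity(origins, 100.0)
        assert vel == pytest.approx(1.93, abs=1e-12)
        assert speed == pytest.approx(1.93, abs=1e-9)

    def test_stationary_zero(self):
        origins = np.zeros((50, 3))
        assert kin.mean_velocity(origins, 100.0) == (0.0, 0.0)

    def test_speed_exceeds_velocity_with_sway(self):
        series, gt = synthetic.simulate_gait(duration=4.0, sway=0.05, seed=4)
        m = kin.analyze_gait(series)
        assert m.velocity == pytest.approx(gt.truth["velocity"], rel=1e-9)
        assert m.mean_speed >= m.velocity


class TestLowpass:
    def test_constant_unchanged(self):
        x = np.full(500, 3.7)
        assert np.allclose(kin.lowpass(x, 5.0, 100.0), x, atol=1e-9)

    def test_tone_above_cutoff_attenuated_20db(self):
        t = np.arange(2000) / 100.0
        tone = np.sin(2 * np.pi * 20.0 * t)
        out = kin.lowpass(tone, 5.0, 100.0)
        core = slice(200, -200)
        assert np.abs(out[core]).max() < 0.1 * np.abs(tone[core]).max()

    def test_tone_below_cutoff_preserved(self):
        t = np.arange(2000) / 100.0
        tone = np.sin(2 * np.pi * 0.5 * t)
        out = kin.lowpass(tone, 5.0, 100.0)
        core = slice(200, -200)
        assert np.abs(out[core]).max() == pytest.approx(1.0, rel=0.01)


class TestTouchdowns:
    def test_noiseless_events_exact(self):
        series, gt = synthetic.simulate_gait(duration=6.25, seed=5)
        events = kin.detect_all_touchdowns(series)
        for limb in kin.LIMB_ORDER:
            assert np.allclose(events[limb], gt.truth["touchdowns"][limb], atol=1e-12)

    def test_constant_height_constant_speed_no_events(self):
        t = np.arange(200) / 100.0
        pos = np.column_stack([t, np.zeros_like(t), np.full_like(t, 0.05)])
        assert len(kin.detect_touchdowns(pos, 100.0)) == 0

    def test_noisy_events_within_two_frames(self):
        series, gt = synthetic.simulate_gait(marker_noise_sd=0.001, duration=6.25, seed=6)
        events = kin.detect_all_touchdowns(series)
        for limb in kin.LIMB_ORDER:
            truth = np.asarray(gt.truth["touchdowns"][limb])
            assert len(events[limb]) == len(truth)
            assert np.max(np.abs(events[limb] - truth)) <= 2.0 / series.frame_rate


def brute_force_cycles(touchdowns):
    """Oracle: state machine over the merged, time-sorted event stream."""
    stream = sorted(
        ((t, kin.LIMB_ORDER.index(limb), limb) for limb in kin.LIMB_ORDER
         for t in np.atleast_1d(touchdowns.get(limb, []))),
    )
    stream = [(t, limb) for t, _, limb in stream]  # simultaneous events in pattern order
    cycles = []
    want = 0
    current = {}
    for t, limb in stream:
        if limb == kin.LIMB_ORDER[want]:
            current[limb] = t
            want += 1
            if want == 4:
                cycles.append(tuple(current[l] for l in kin.LIMB_ORDER))
                want = 0
                current = {}
    return cycles


class TestGaitCycles:
    def test_single_sequence(self):
        cycles = kin.segment_gait_cycles(
            {"LH": [0.0], "LF": [0.2], "RH": [0.4], "RF": [0.6]}
        )
        assert len(cycles) == 1 and cycles[0].complete
        assert (cycles[0].start, cycles[0].end) == (0.0, 0.6)

    def test_wrong_order_yields_no_complete_cycle(self):
        cycles = kin.segment_gait_cycles(
            {"RF": [0.0], "RH": [0.1], "LF": [0.2], "LH": [0.3]}
        )
        assert sum(c.complete for c in cycles) == 0

    def test_ten_programmed_strides(self):
        series, gt = synthetic.simulate_gait(duration=10.25, seed=7)
        events = kin.detect_all_touchdowns(series)
        cycles = kin.segment_gait_cycles(events)
        assert sum(c.complete for c in cycles) == gt.truth["n_cycles"] == 10

    @given(
        st.fixed_dictionaries(
            {
                limb: st.lists(st.integers(0, 30), max_size=8).map(
                    lambda v: sorted(set(v))
                )
                for limb in kin.LIMB_ORDER
            }
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, touchdowns):
        got = [
            (c.lh, c.lf, c.rh, c.rf)
            for c in kin.segment_gait_cycles(
                {k: np.asarray(v, float) for k, v in touchdowns.items()}
            )
            if c.complete
        ]
        expected = [tuple(float(x) for x in cyc) for cyc in brute_force_cycles(touchdowns)]
        assert got == expected


class TestFullPipeline:
    def test_parameter_recovery_noiseless(self):
        series, gt = synthetic.simulate_gait(seed=8)
        m = kin.analyze_gait(series)
        for pod in ("head", "shoulders", "rear"):
            assert m.ranges[pod]["yaw"] == pytest.approx(30.0, abs=1e-3)
            assert m.ranges[pod]["pitch"] == pytest.approx(17.0, abs=1e-3)
            assert m.ranges[pod]["roll"] == pytest.approx(12.0, abs=1e-3)
        assert m.velocity == pytest.approx(1.93, rel=1e-6)
        assert m.n_cycles == gt.truth["n_cycles"]
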