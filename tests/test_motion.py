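"""Motion-stream processing: conversion, filtering, gaps, flips, forces."""

import numpy as np
import pytest

from mrsim.errors import InvalidArgumentError
from mrsim.geom import expmap_to_quaternion, geodesic_angle
from mrsim.motion import (
    ForceTrace,
    MotionFrame,
    MotionStream,
    RawPose,
    convert_frame,
    detect_orientation_flips,
    fill_occlusions,
    lowpass,
    lowpass_gain,
    monitor_force,
)

from .oracles import count_upcrossings, onepole_steady_amplitude


def make_stream(translations, rotvecs=None, obj="obj", rate=200.0):
    """Stream from a list of translations (None = occluded frame)."""
    frames = []
    for k, t in enumerate(translations):
        frame = MotionFrame(k, k / rate)
        if t is not None:
            r = rotvecs[k] if rotvecs is not None else (0.0, 0.0, 0.0)
            frame.poses[obj] = RawPose(t, r)
        frames.append(frame)
    return MotionStream(frames, nominal_rate=rate)


class TestConvertFrame:
    def test_mm_to_cm_default(self):
        frame = MotionFrame(0, 0.0, {"a": RawPose([100, 0, 0], [0, 0, 0])})
        pose = convert_frame(frame)["a"]
        np.testing.assert_allclose(pose.translation, [10, 0, 0])
        np.testing.assert_allclose(pose.rotation, [1, 0, 0, 0])

    def test_scale_one_is_identity_on_translation(self):
        frame = MotionFrame(0, 0.0, {"a": RawPose([7, -3, 2], [0.1, 0.2, 0.3])})
        np.testing.assert_allclose(convert_frame(frame, 1.0)["a"].translation, [7, -3, 2])

    def test_scale_roundtrip(self, rng):
        for _ in range(20):
            t = rng.normal(size=3) * 100
            frame = MotionFrame(0, 0.0, {"a": RawPose(t, rng.normal(size=3))})
            down = convert_frame(frame, 0.1)["a"].translation
            np.testing.assert_allclose(down * 10, t, atol=1e-12)

    def test_commutes_with_rigid_offset(self, rng):
        """Scaling then composing a fixed offset equals composing then scaling
        (matrix oracle on homogeneous coordinates)."""
        from mrsim.geom import RigidTransform, quat_to_matrix

        offset = RigidTransform(expmap_to_quaternion(rng.normal(size=3)), rng.normal(size=3))
        for _ in range(20):
            t = rng.normal(size=3) * 100
            r = rng.normal(size=3)
            frame = MotionFrame(0, 0.0, {"a": RawPose(t, r)})
            pose = convert_frame(frame, 0.1)["a"]
            scene = RigidTransform(pose.rotation, pose.translation).compose(
                RigidTransform(offset.rotation, offset.translation * 0.1)
            )
            m_raw = RigidTransform(expmap_to_quaternion(r), t).compose(offset).matrix
            m_raw[:3, 3] *= 0.1
            np.testing.assert_allclose(scene.matrix, m_raw, atol=1e-9)


class TestLowpass:
    def test_constant_stream_unchanged(self):
        s = make_stream([[1.0, 2.0, 3.0]] * 20, rotvecs=[[0.3, 0, 0]] * 20)
        out = lowpass(s, 0.3)
        for f in out.frames:
            np.testing.assert_allclose(f.poses["obj"].translation, [1, 2, 3], atol=1e-12)
            np.testing.assert_allclose(f.poses["obj"].rotation_vector, [0.3, 0, 0], atol=1e-9)

    def test_alpha_one_identity(self, rng):
        trans = [rng.normal(size=3) for _ in range(30)]
        rots = [rng.normal(size=3) * 0.5 for _ in range(30)]
        s = make_stream(trans, rotvecs=rots)
        out = lowpass(s, 1.0)
        for fin, fout in zip(s.frames, out.frames):
            np.testing.assert_allclose(
                fout.poses["obj"].translation, fin.poses["obj"].translation, atol=1e-12
            )
            qa = expmap_to_quaternion(fin.poses["obj"].rotation_vector)
            qb = expmap_to_quaternion(fout.poses["obj"].rotation_vector)
            assert geodesic_angle(qa, qb) < 1e-9

    @pytest.mark.parametrize("alpha", [0.1, 0.2, 0.5, 0.9])
    def test_nyquist_attenuation_closed_form(self, alpha):
        """Steady-state amplitude of a Nyquist alternation equals the one-pole
        magnitude response a/(2-a), cross-checked by simulation."""
        n = 400
        trans = [[(1.0 if k % 2 == 0 else -1.0), 0.0, 0.0] for k in range(n)]
        out = lowpass(make_stream(trans), alpha)
        amp = max(abs(f.poses["obj"].translation[0]) for f in out.frames[n // 2 :])
        gain = lowpass_gain(alpha, np.pi)
        assert gain == pytest.approx(alpha / (2.0 - alpha), abs=1e-12)
        assert amp == pytest.approx(gain, abs=1e-6)
        assert amp == pytest.approx(onepole_steady_amplitude(alpha), abs=1e-9)

    def test_dc_gain_exactly_one(self):
        assert lowpass_gain(0.37, 0.0) == pytest.approx(1.0, abs=1e-15)

    def test_preserves_metadata_and_unit_rotations(self, rng):
        trans = [rng.normal(size=3) for _ in range(25)]
        rots = [rng.normal(size=3) for _ in range(25)]
        s = make_stream(trans, rotvecs=rots)
        out = lowpass(s, 0.25)
        assert out.nominal_rate == s.nominal_rate
        assert [f.timestamp for f in out.frames] == [f.timestamp for f in s.frames]
        for f in out.frames:
            q = expmap_to_quaternion(f.poses["obj"].rotation_vector)
            assert np.linalg.norm(q) == pytest.approx(1.0, abs=1e-9)

    def test_smoothing_reduces_noise_rmse(self, rng):
        """Vibration-removal regime: slow voluntary motion (cm-scale at a
        fraction of a hertz, sampled at 200 Hz) plus measurement noise. With
        a tuned smoothing factor the filter beats the raw stream at every
        noise level."""
        n = 600
        t = np.arange(n) / 200.0
        clean = np.stack(
            [15 * np.sin(2 * np.pi * 0.1 * t),
             15 * np.cos(2 * np.pi * 0.13 * t),
             10 * np.sin(2 * np.pi * 0.07 * t)],
            axis=1,
        )
        for sigma in (0.1, 0.5, 1.0):
            noisy = clean + rng.normal(scale=sigma, size=clean.shape)
            rmse_raw = np.sqrt(np.mean((noisy - clean) ** 2))
            rmse_tuned = min(
                np.sqrt(np.mean((np.array(
                    [f.poses["obj"].translation
                     for f in lowpass(make_stream(list(noisy)), alpha).frames]
                ) - clean) ** 2))
                for alpha in (0.1, 0.2, 0.3, 0.5, 0.7)
            )
            assert rmse_tuned < rmse_raw

    def test_alpha_out_of_range(self):
        s = make_stream([[0, 0, 0]] * 3)
        for alpha in (0.0, -0.1, 1.5):
            with pytest.raises(InvalidArgumentError):
                lowpass(s, alpha)


class TestFillOcclusions:
    def test_complete_stream_untouched(self, rng):
        s = make_stream([rng.normal(size=3) for _ in range(10)])
        out, gaps = fill_occlusions(s, 3)
        assert gaps == []
        for fin, fout in zip(s.frames, out.frames):
            np.testing.assert_array_equal(
                fout.poses["obj"].translation, fin.poses["obj"].translation
            )

    def test_single_gap_midpoint(self):
        s = make_stream([[0, 0, 0], None, [2, 0, 0]])
        out, gaps = fill_occlusions(s, 3)
        np.testing.assert_allclose(out.frames[1].poses["obj"].translation, [1, 0, 0])
        assert len(gaps) == 1 and gaps[0].reason == "filled"

    def test_rotation_gap_slerp(self):
        s = make_stream(
            [[0, 0, 0], None, [0, 0, 0]],
            rotvecs=[[0, 0, 0], None, [np.pi / 2, 0, 0]],
        )
        out, _ = fill_occlusions(s, 3)
        q = expmap_to_quaternion(out.frames[1].poses["obj"].rotation_vector)
        assert geodesic_angle(q, expmap_to_quaternion([np.pi / 4, 0, 0])) < 1e-9

    def test_long_gap_unresolved(self):
        s = make_stream([[0, 0, 0]] + [None] * 5 + [[6, 0, 0]])
        out, gaps = fill_occlusions(s, 3)
        assert all("obj" not in out.frames[k].poses for k in range(1, 6))
        assert len(gaps) == 1 and gaps[0].reason == "too-long" and gaps[0].length == 5

    def test_boundary_gap_not_extrapolated(self):
        s = make_stream([None, [1, 0, 0], [2, 0, 0], None])
        out, gaps = fill_occlusions(s, 3)
        assert "obj" not in out.frames[0].poses
        assert "obj" not in out.frames[3].poses
        assert {g.reason for g in gaps} == {"boundary"}

    def test_idempotent_and_preserves_originals(self, rng):
        trans = [rng.normal(size=3) if k % 4 else None for k in range(16)]
        trans[0] = rng.normal(size=3)
        trans[-1] = rng.normal(size=3)
        s = make_stream(trans)
        once, _ = fill_occlusions(s, 2)
        twice, gaps2 = fill_occlusions(once, 2)
        for f1, f2 in zip(once.frames, twice.frames):
            assert set(f1.poses) == set(f2.poses)
            for k in f1.poses:
                np.testing.assert_array_equal(f1.poses[k].translation, f2.poses[k].translation)
        for k, t in enumerate(trans):
            if t is not None:
                np.testing.assert_array_equal(once.frames[k].poses["obj"].translation, t)


class TestDetectFlips:
    def test_smooth_rotation_clean(self):
        rots = [[np.deg2rad(k), 0, 0] for k in range(60)]
        s = make_stream([[0, 0, 0]] * 60, rotvecs=rots)
        assert detect_orientation_flips(s) == []

    def test_injected_flip_flagged(self):
        """A persistent upside-down flip is flagged exactly at its onset."""
        rots = [[0.01 * k, 0, 0] for k in range(30)]
        for k in range(17, 30):  # tracker re-solves the object upside down
            rots[k] = [0.01 * k + np.pi, 0, 0]
        s = make_stream([[0, 0, 0]] * 30, rotvecs=rots)
        assert detect_orientation_flips(s, np.pi / 2) == [17]

    def test_matches_bruteforce_scan(self, rng):
        rots = [rng.normal(size=3) for _ in range(50)]
        s = make_stream([[0, 0, 0]] * 50, rotvecs=rots)
        thr = 1.0
        expected = []
        qs = [expmap_to_quaternion(r) for r in rots]
        for k in range(1, 50):
            if geodesic_angle(qs[k - 1], qs[k]) > thr:
                expected.append(k)
        assert detect_orientation_flips(s, thr) == expected


class TestMonitorForce:
    def test_ramp_first_warning_after_20N(self):
        """On a 0..40 N unit-step ramp the first warning is the 21 N sample."""
        forces = np.arange(0.0, 41.0)
        trace = ForceTrace(np.arange(41.0) * 0.1, forces)
        events = monitor_force(trace)  # default threshold: 20 N critical force
        assert len(events) == 1
        assert events[0].force == pytest.approx(21.0)
        assert events[0].threshold == pytest.approx(20.0)

    def test_sample_exactly_at_threshold_does_not_warn(self):
        trace = ForceTrace([0.0, 1.0], [20.0, 20.0])
        assert monitor_force(trace) == []

    def test_constant_excursion_single_event(self):
        trace = ForceTrace(np.arange(5.0), [10.0] * 5)
        events = monitor_force(trace, threshold=5.0)
        assert len(events) == 1 and events[0].timestamp == 0.0

    def test_event_count_matches_bruteforce(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 60))
            forces = rng.uniform(0, 40, size=n)
            trace = ForceTrace(np.arange(n, dtype=float), forces)
            assert len(monitor_force(trace)) == count_upcrossings(forces, 20.0)

    def test_events_match_upcrossings_property(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(deadline=None, derandomize=True, max_examples=60)
        @given(st.lists(st.floats(min_value=0.0, max_value=40.0,
                                  allow_nan=False), min_size=1, max_size=40))
        def check(forces):
            arr = np.array(forces)
            trace = ForceTrace(np.arange(len(arr), dtype=float), arr)
            assert len(monitor_force(trace)) == count_upcrossings(arr, 20.0)

        check()

    def test_empty_trace_and_bad_threshold(self):
        with pytest.raises(InvalidArgumentError):
            monitor_force(ForceTrace([0.0], [1.0]), threshold=0.0)


class TestStreamCsv:
    def test_roundtrip_with_dropout(self, tmp_path, rng):
        trans = [rng.normal(size=3) * 10 if k % 3 else None for k in range(9)]
        trans[0] = rng.normal(size=3)
        s = make_stream(trans)
        path = tmp_path / "capture.csv"
        s.to_csv(path)
        back = MotionStream.from_csv(path)
        assert len(back.frames) == len(s.frames)
        for fin, fout in zip(s.frames, back.frames):
            assert set(fin.poses) == set(fout.poses)
            for k in fin.poses:
                np.testing.assert_allclose(
                    fout.poses[k].translation, fin.poses[k].translation, atol=1e-7
                )

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("frame,time_s\n0,0.0\n")
        from mrsim.errors import FileFormatError

        with pytest.raises(FileFormatError):
            MotionStream.from_csv(p)


def test_stream_invariants():
    with pytest.raises(InvalidArgumentError):
        MotionStream([], 200.0)
    f0, f1 = MotionFrame(0, 0.0), MotionFrame(1, 0.0)  # equal timestamps
    with pytest.raises(InvalidArgumentError):
        MotionStream([f0, f1], 200.0)
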