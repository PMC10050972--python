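import numpy as np
import pytest
from hypothesis import given, strategies as st

from nirchar.io import (
    read_pose_csv,
    read_synced_csv,
    read_traces_csv,
    write_pose_csv,
    write_synced_csv,
    write_traces_csv,
)
from nirchar.presets import MotionProfile, default_motion_profile
from nirchar.records import IntensityTrace, PoseTrack
from nirchar.simulate import generate_pose_track
from nirchar.sync import (
    TapNotFoundError,
    concentration_from_dose,
    detect_tap,
    euclidean_distance,
    split_by_direction,
    synchronize,
)

coord = st.floats(-500, 500, allow_nan=False, allow_infinity=False)
point = st.tuples(coord, coord, coord)


class TestEuclideanDistance:
    def test_identity_and_pythagorean_triple(self):
        assert euclidean_distance((0, 0, 0), (0, 0, 0)) == 0.0
        assert euclidean_distance((3, 4, 0), (0, 0, 0)) == pytest.approx(5.0)

    @given(point, point)
    def test_matches_term_by_term_oracle(self, a, b):
        oracle = sum((ai - bi) ** 2 for ai, bi in zip(a, b)) ** 0.5
        assert euclidean_distance(a, b) == pytest.approx(oracle, abs=1e-9)

    @given(point, point, point)
    def test_symmetry_and_triangle_inequality(self, a, b, c):
        ab = euclidean_distance(a, b)
        assert ab == euclidean_distance(b, a)
        assert ab <= euclidean_distance(a, c) + euclidean_distance(c, b) + 1e-9

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            euclidean_distance((np.nan, 0, 0), (0, 0, 0))


def _tapped_track(noise_mm=0.0, tap_time=2.0, seed=0):
    profile = MotionProfile(
        regime="static_episodic", distance_waypoints=(200.0,), dwell_s=6.0,
        tap_time=tap_time, noise_mm=noise_mm, lateral_wobble_mm=0.0,
    )
    return generate_pose_track(profile, seed=seed)


class TestDetectTap:
    def test_finds_injected_tap_within_one_pose_frame(self):
        track = _tapped_track()
        assert detect_tap(track) == pytest.approx(2.0, abs=0.025)

    def test_constant_track_raises(self):
        n = 200
        track = PoseTrack(
            t=np.arange(n) / 40.0, x=np.zeros(n), y=np.zeros(n),
            z=np.full(n, 300.0), angle=np.full(n, 90.0), fps=40.0,
        )
        with pytest.raises(TapNotFoundError):
            detect_tap(track)

    def test_manual_override_bypasses_detection(self):
        n = 200
        track = PoseTrack(
            t=np.arange(n) / 40.0, x=np.zeros(n), y=np.zeros(n),
            z=np.full(n, 300.0), angle=np.full(n, 90.0), fps=40.0,
        )
        assert detect_tap(track, manual_time=1.25) == 1.25

    def test_detection_robust_to_positional_noise(self):
        # tap at 2.0 s under 0.5 mm noise: within +/-2 pose frames on
        # at least 95 of 100 seeds
        hits = 0
        for seed in range(100):
            track = _tapped_track(noise_mm=0.5, seed=seed)
            try:
                if abs(detect_tap(track) - 2.0) <= 2 / 40.0 + 1e-9:
                    hits += 1
            except TapNotFoundError:
                pass
        assert hits >= 95


def _linear_pose(d0=100.0, rate=10.0, duration=10.0, fps=40.0):
    n = int(duration * fps) + 1
    t = np.arange(n) / fps
    d = d0 + rate * t
    return PoseTrack(
        t=t, x=np.zeros(n), y=np.zeros(n), z=d, angle=np.full(n, 90.0), fps=fps
    )


def _video_trace(t0, t1, fps=30.0, value=50.0):
    n = int((t1 - t0) * fps) + 1
    t = t0 + np.arange(n) / fps
    return IntensityTrace(roi_id="roi0", t=t, intensity=np.full(n, value), fps=fps)


class TestSynchronize:
    def test_linear_distance_interpolates_exactly(self):
        track = _linear_pose()
        trace = _video_trace(0.5, 9.5)
        s = synchronize(trace, track, tap_trace=1.0, tap_track=1.0, mask_tap_s=0.0)
        assert np.allclose(s["distance"], 100.0 + 10.0 * s["t"], atol=1e-9)

    def test_identical_timebases_pass_distances_through(self):
        track = _linear_pose(fps=40.0)
        trace = IntensityTrace(
            roi_id="r", t=track.t, intensity=np.full(len(track), 10.0), fps=40.0
        )
        s = synchronize(trace, track, tap_trace=2.0, tap_track=2.0, mask_tap_s=0.0)
        assert np.allclose(s["distance"], track.distance, atol=1e-12)

    def test_shift_equivariance(self):
        track = _linear_pose()
        trace = _video_trace(0.5, 9.5)
        ref = synchronize(trace, track, tap_trace=1.0, tap_track=1.0, mask_tap_s=0.0)
        delta = 3.7
        shifted = PoseTrack(
            t=track.t + delta, x=track.x, y=track.y, z=track.z,
            angle=track.angle, fps=track.fps,
        )
        out = synchronize(
            trace, shifted, tap_trace=1.0, tap_track=1.0 + delta, mask_tap_s=0.0
        )
        assert np.allclose(ref["distance"], out["distance"], atol=1e-9)
        assert np.allclose(ref["t"], out["t"], atol=1e-12)

    def test_never_extrapolates(self):
        track = _linear_pose(duration=5.0)
        trace = _video_trace(0.0, 20.0)
        s = synchronize(trace, track, tap_trace=1.0, tap_track=1.0, mask_tap_s=0.0)
        assert s["t"].min() >= track.t[0] - 1e-12
        assert s["t"].max() <= track.t[-1] + 1e-12
        assert s.provenance["n_dropped"] > 0

    def test_velocity_integrates_to_path_length(self):
        profile = default_motion_profile("slow", noise_mm=0.2)
        track = generate_pose_track(profile, seed=3)
        trace = _video_trace(0.5, track.t[-1] - 0.5, fps=30.0)
        s = synchronize(trace, track, tap_trace=2.0, tap_track=2.0, mask_tap_s=0.0)
        path = np.sum(np.abs(np.diff(s["distance"])))
        integral = np.sum(s["velocity"][1:] * np.diff(s["t"]))
        assert integral == pytest.approx(path, rel=1e-6)

    def test_static_dwells_match_generator_schedule(self):
        profile = default_motion_profile("static_episodic", noise_mm=0.0)
        track = generate_pose_track(profile, seed=4)
        trace = _video_trace(0.5, track.t[-1] - 0.5, fps=30.0)
        s = synchronize(trace, track, tap_trace=2.0, tap_track=2.0)
        checked = 0
        for t0, t1, kind in track.truth.segments:
            if kind != "dwell":
                continue
            inside = (s["t"] > t0 + 0.5) & (s["t"] < t1 - 0.5)
            if inside.any():
                assert np.all(s["velocity"][inside] < 0.1)
                assert np.all(s["direction"][inside] == "static")
                checked += 1
        assert checked >= 3

    def test_empty_result_after_masking_raises(self):
        from nirchar.sync import NoOverlapError

        track = _linear_pose(duration=5.0)
        trace = _video_trace(0.0, 1.0)
        with pytest.raises(NoOverlapError):
            synchronize(trace, track, tap_trace=0.5, tap_track=0.5, mask_tap_s=10.0)

    def test_tap_outside_recording_rejected(self):
        track = _linear_pose(duration=5.0)
        trace = _video_trace(0.0, 5.0)
        with pytest.raises(ValueError, match="tap_track"):
            synchronize(trace, track, tap_trace=1.0, tap_track=7.0)


class TestSplitByDirection:
    def test_monotone_decrease_is_all_approach(self):
        track = _linear_pose(d0=400.0, rate=-10.0)
        trace = _video_trace(0.5, 9.5)
        s = synchronize(trace, track, tap_trace=1.0, tap_track=1.0, mask_tap_s=0.0)
        approach, retreat = split_by_direction(s)
        assert len(retreat) == 0
        assert len(approach) == len(s)

    def test_triangle_wave_switches_at_apex(self):
        fps = 40.0
        n = int(20 * fps) + 1
        t = np.arange(n) / fps
        d = np.where(t <= 10.0, 400.0 - 20.0 * t, 200.0 + 20.0 * (t - 10.0))
        track = PoseTrack(
            t=t, x=np.zeros(n), y=np.zeros(n), z=d, angle=np.full(n, 90.0), fps=fps
        )
        trace = _video_trace(0.5, 19.5, fps=30.0)
        s = synchronize(trace, track, tap_trace=1.0, tap_track=1.0, mask_tap_s=0.0)
        approach, retreat = split_by_direction(s)
        # switch happens within the smoothing half-window (0.25 s) of t = 10
        assert approach["t"].max() <= 10.0 + 0.3
        assert retreat["t"].min() >= 10.0 - 0.3

    def test_constant_distance_yields_empty_subsets(self):
        track = _linear_pose(rate=0.0)
        trace = _video_trace(0.5, 9.5)
        s = synchronize(trace, track, tap_trace=1.0, tap_track=1.0, mask_tap_s=0.0)
        approach, retreat = split_by_direction(s)
        assert len(approach) == 0 and len(retreat) == 0


class TestConcentrationFromDose:
    def test_reference_clinical_dose(self):
        # 0.1 mg/kg in 70 kg at 70 ml/kg blood volume: 7 mg in 4.9 l
        c = concentration_from_dose(0.1, 70.0, 70.0)
        assert c == pytest.approx(0.0014286, abs=1e-6)
        assert float(f"{c:.2g}") == 0.0014

    def test_weight_cancels(self):
        assert concentration_from_dose(1.0, 55.0, 1000.0) == pytest.approx(0.001)

    def test_hand_computed_case(self):
        # 0.5 mg/kg, 80 kg, 70 ml/kg -> 40 mg / 5600 ml
        assert concentration_from_dose(0.5, 80.0, 70.0) == pytest.approx(
            40.0 / 5600.0
        )

    @pytest.mark.parametrize("args", [(-1, 70, 70), (0.1, 0, 70), (0.1, 70, -5)])
    def test_rejects_non_positive_inputs(self, args):
        with pytest.raises(ValueError):
            concentration_from_dose(*args)


class TestCsvRoundTrips:
    def test_pose_round_trip(self, tmp_path):
        track = _tapped_track(noise_mm=0.2, seed=1)
        path = write_pose_csv(track, tmp_path / "pose.csv")
        back = read_pose_csv(path)
        assert np.allclose(back.distance, track.distance, atol=1e-5)
        assert back.fps == pytest.approx(track.fps, rel=1e-6)

    def test_trace_round_trip_preserves_rois_and_zones(self, tmp_path):
        traces = [
            IntensityTrace(
                roi_id=f"roi{i}", t=np.arange(50) / 25.0,
                intensity=np.full(50, 10.0 * (i + 1)), fps=25.0, zone=1 + i % 3,
            )
            for i in range(3)
        ]
        path = write_traces_csv(traces, tmp_path / "traces.csv")
        back = read_traces_csv(path)
        assert [tr.roi_id for tr in back] == ["roi0", "roi1", "roi2"]
        assert [tr.zone for tr in back] == [1, 2, 3]
        assert np.allclose(back[1].intensity, 20.0)

    def test_reader_tolerates_extra_columns(self, tmp_path):
        track = _tapped_track(seed=2)
        path = write_pose_csv(track, tmp_path / "pose.csv")
        import pandas as pd

        df = pd.read_csv(path)
        df["extra"] = 1
        df.to_csv(path, index=False)
        back = read_pose_csv(path)
        assert len(back) == len(track)

    def test_synced_round_trip(self, tmp_path):
        track = _linear_pose()
        trace = _video_trace(0.5, 9.5)
        s = synchronize(trace, track, tap_trace=1.0, tap_track=1.0, mask_tap_s=0.0)
        path = write_synced_csv(s, tmp_path / "synced.csv")
        back = read_synced_csv(path)
        assert np.allclose(back["distance"], s["distance"], atol=1e-5)
        assert list(back["direction"]) == list(s["direction"])
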