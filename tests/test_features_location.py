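import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics.pairwise import haversine_distances

from motionloc.errors import ParameterError, SchemaError, UndefinedMetricError
from motionloc.features_location import (
    EARTH_RADIUS_M,
    MfccConfig,
    accel_magnitude,
    detect_steps,
    extract_localization_features,
    filterbank_centers_hz,
    forward_bearing,
    haversine_m,
    heading_angle,
    mel_filterbank,
    mel_scale,
    mfcc,
    pre_emphasis,
    trajectory_features,
)


class TestPreEmphasis:
    def test_alpha_zero_is_identity(self, rng):
        x = rng.normal(size=64)
        assert np.array_equal(pre_emphasis(x, 0.0), x)

    def test_constant_input(self):
        out = pre_emphasis(np.full(5, 2.0), 0.97)
        assert out[0] == 2.0
        assert np.allclose(out[1:], 0.06)

    def test_unit_impulse(self):
        out = pre_emphasis(np.array([1.0, 0.0, 0.0, 0.0]), 0.97)
        assert np.allclose(out, [1.0, -0.97, 0.0, 0.0])

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ParameterError):
            pre_emphasis(np.zeros(4), 1.0)


class TestMelScale:
    def test_zero_maps_to_zero(self):
        assert mel_scale(0.0) == 0.0

    def test_700_hz(self):
        assert mel_scale(700.0) == pytest.approx(2595.0 * np.log10(2.0), abs=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(pair=st.tuples(st.floats(0.0, 20000.0), st.floats(0.0, 20000.0)))
    def test_strictly_increasing(self, pair):
        lo, hi = sorted(pair)
        if lo < hi:
            assert mel_scale(lo) < mel_scale(hi)

    def test_filterbank_covers_spectrum_without_gaps(self):
        fb = mel_filterbank(26, 512, 8000.0)
        assert np.all(fb.sum(axis=1) > 0)
        # every interior FFT bin is seen by at least one filter
        coverage = fb.sum(axis=0)
        assert np.all(coverage[1:-1] > 0)


class TestMfcc:
    def test_pure_tone_lands_in_matching_filter(self):
        sr, f0 = 8000.0, 1000.0
        t = np.arange(int(sr)) / sr
        tone = np.sin(2 * np.pi * f0 * t)
        cfg = MfccConfig()
        frame_len = int(round(cfg.frame_s * sr))
        n_fft = 1 << max(frame_len - 1, 1).bit_length()
        fb = mel_filterbank(cfg.n_mel_filters, n_fft, sr)
        frames = tone[: frame_len * 10].reshape(10, frame_len) * np.hamming(frame_len)
        power = np.abs(np.fft.rfft(frames, n=n_fft, axis=1)) ** 2
        energies = (power @ fb.T).mean(axis=0)
        centers = filterbank_centers_hz(cfg.n_mel_filters, sr)
        assert abs(centers[int(np.argmax(energies))] - f0) == np.min(np.abs(centers - f0))

    def test_silence_gives_finite_identical_frames(self):
        out = mfcc(np.zeros(4000), 8000.0)
        assert np.all(np.isfinite(out))
        assert np.max(np.abs(out - out[0])) < 1e-9

    def test_gain_shifts_only_first_coefficient(self, rng):
        x = rng.normal(size=8000)
        a = mfcc(x, 8000.0)
        b = mfcc(2.0 * x, 8000.0)
        assert np.max(np.abs(a[:, 1:] - b[:, 1:])) < 1e-6
        assert np.all(b[:, 0] > a[:, 0])

    def test_too_short_audio_rejected(self):
        with pytest.raises(ParameterError):
            mfcc(np.zeros(10), 8000.0)


class TestAccelMagnitude:
    def test_three_four_five(self):
        assert accel_magnitude([3.0], [4.0], [0.0])[0] == 5.0

    def test_zero_vector(self):
        assert accel_magnitude([0.0], [0.0], [0.0])[0] == 0.0

    def test_rotation_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        v = rng.normal(size=(50, 3))
        m0 = accel_magnitude(v[:, 0], v[:, 1], v[:, 2])
        rot = Rotation.random(random_state=7).as_matrix()
        w = v @ rot.T
        m1 = accel_magnitude(w[:, 0], w[:, 1], w[:, 2])
        assert np.max(np.abs(m0 - m1)) < 1e-9

    def test_length_mismatch_rejected(self):
        with pytest.raises(SchemaError):
            accel_magnitude([1.0, 2.0], [1.0], [1.0])


class TestDetectSteps:
    def test_constant_magnitude_has_no_steps(self):
        assert len(detect_steps(np.full(320, 9.81), 32.0)) == 0

    def test_two_hz_gait_over_ten_seconds(self):
        t = np.arange(320) / 32.0
        mag = 9.81 + 2.0 * np.sin(2 * np.pi * 2.0 * t)
        steps = detect_steps(mag, 32.0)
        assert abs(len(steps) - 20) <= 1

    def test_subthreshold_ripple_ignored(self, rng):
        t = np.arange(320) / 32.0
        mag = 9.81 + 2.0 * np.sin(2 * np.pi * 2.0 * t) + 0.01 * rng.normal(size=320)
        # ripple peaks are far below the prominence bound relative to std
        high_bar = detect_steps(mag, 32.0, min_prominence_factor=5.0)
        assert len(high_bar) == 0

    def test_step_count_scales_with_gait_cycles(self):
        for seconds in (5, 10, 20):
            t = np.arange(int(seconds * 32)) / 32.0
            mag = 9.81 + 2.0 * np.sin(2 * np.pi * 2.0 * t)
            count = len(detect_steps(mag, 32.0))
            assert count == pytest.approx(2.0 * seconds, rel=0.05, abs=1)


class TestHeadingAngle:
    @pytest.mark.parametrize(
        "a, b, expected", [(1.0, 0.0, 0.0), (0.0, 1.0, 90.0), (-1.0, 0.0, 180.0)]
    )
    def test_cardinal_directions(self, a, b, expected):
        assert heading_angle(a, b) == pytest.approx(expected, abs=1e-12)

    def test_zero_field_rejected(self):
        with pytest.raises(UndefinedMetricError):
            heading_angle(0.0, 0.0)

    def test_range(self, rng):
        for a, b in rng.normal(size=(50, 2)):
            if (a, b) != (0.0, 0.0):
                assert -180.0 <= heading_angle(a, b) <= 180.0


class TestTrajectory:
    def test_haversine_matches_sklearn(self, rng):
        pts = np.column_stack(
            [rng.uniform(-80, 80, size=10), rng.uniform(-170, 170, size=10)]
        )
        ours = np.array(
            [haversine_m(*pts[i], *pts[j]) for i in range(10) for j in range(10)]
        ).reshape(10, 10)
        ref = haversine_distances(np.radians(pts)) * EARTH_RADIUS_M
        assert np.max(np.abs(ours - ref)) < 1e-6

    def test_haversine_close_to_planar_for_short_legs(self):
        lat = 47.0
        d = haversine_m(lat, 8.0, lat, 8.0 + 0.01)  # ~760 m east
        planar = np.radians(0.01) * EARTH_RADIUS_M * np.cos(np.radians(lat))
        assert abs(d - planar) / planar < 0.005

    def test_stationary_track_has_zero_motion(self):
        track = np.column_stack([np.arange(10.0), np.full(10, 47.0), np.full(10, 8.0)])
        tf = trajectory_features(track)
        assert tf.total_distance_m == 0.0
        assert tf.max_displacement_m == 0.0
        assert tf.direction_change_sum_deg == 0.0

    def test_straight_east_track(self):
        # 10 m/s due east for 60 s
        speed, lat = 10.0, 47.0
        deg_per_m = np.degrees(1.0 / (EARTH_RADIUS_M * np.cos(np.radians(lat))))
        t = np.arange(61.0)
        track = np.column_stack([t, np.full(61, lat), 8.0 + speed * t * deg_per_m])
        tf = trajectory_features(track)
        assert tf.total_distance_m == pytest.approx(600.0, rel=1e-3)
        assert tf.average_speed_ms == pytest.approx(10.0, rel=1e-3)
        assert tf.direction_change_sum_deg < 1.0

    def test_square_path_turns_270_degrees(self):
        # four equal 100 m legs: east, north, west, south -> three 90 deg turns
        lat0, lon0 = 0.0, 8.0  # equator keeps the geometry clean
        deg = np.degrees(100.0 / EARTH_RADIUS_M)
        corners = [
            (lat0, lon0), (lat0, lon0 + deg), (lat0 + deg, lon0 + deg),
            (lat0 + deg, lon0), (lat0, lon0),
        ]
        track = np.array([(i, lat, lon) for i, (lat, lon) in enumerate(corners)])
        tf = trajectory_features(track)
        assert tf.direction_change_sum_deg == pytest.approx(270.0, abs=0.5)

    def test_short_track_yields_zeros(self):
        tf = trajectory_features(np.array([[0.0, 47.0, 8.0]]))
        assert tf.total_distance_m == 0.0 and tf.average_speed_ms == 0.0

    def test_bearing_east(self):
        assert forward_bearing(0.0, 8.0, 0.0, 8.001) == pytest.approx(90.0, abs=1e-6)


class TestExtractLocalizationFeatures:
    def test_column_count(self, localization_windows):
        names, values = extract_localization_features(localization_windows[0])
        assert len(names) == len(values) == 6 + 2 * 9 + 13 + 2

    def test_missing_audio_gives_neutral_fill_and_flag(self, localization_windows):
        w = localization_windows[0].copy()
        w.audio = None
        names, values = extract_localization_features(w)
        row = dict(zip(names, values))
        assert row["audio_missing"] == 1.0
        assert all(row[f"mfcc[{k}]"] == 0.0 for k in range(13))

    def test_identical_windows_give_identical_rows(self, localization_windows):
        w = localization_windows[0]
        _, a = extract_localization_features(w)
        _, b = extract_localization_features(w)
        assert np.array_equal(a, b)

    def test_missing_accelerometer_is_schema_error(self, localization_windows):
        w = localization_windows[0].copy()
        del w.channels["acc_x"]
        with pytest.raises(SchemaError, match="acc_x"):
            extract_localization_features(w)
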