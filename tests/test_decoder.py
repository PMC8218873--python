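"""Feature extraction, Kalman decoding, click classification, Grid Task."""

import numpy as np
import pytest

from bcilink import decoder as dec
from bcilink.decoder import (
    GridTaskConfig,
    KalmanDecoder,
    bitrate_bps,
    calibrate_from_user,
    calibrate_kalman,
    classify_click,
    extract_features,
    make_synthetic_user,
    performance_metrics,
    run_grid_task,
    train_click_classifier,
    typing_rate_ccpm,
)

FS = 30_000.0


class TestExtractFeatures:
    def test_silent_stream_yields_zero_features(self):
        ff = extract_features(np.zeros((3, 60_000)), FS)
        assert not ff.counts.any() and not ff.power.any()
        assert ff.counts.shape == (100, 3)

    def test_known_spike_train_is_binned_correctly(self):
        x = np.zeros((1, 60_000))
        spike_at = np.array([5_000, 10_000, 10_300, 45_000])
        for i in spike_at:
            x[0, i:i + 15] = -120.0
        ff = extract_features(x, FS, thresholds_uv=np.array([-50.0]))
        bins = spike_at // 600  # 20 ms bins at 30 kS/s
        expect = np.zeros(100)
        np.add.at(expect, bins, 1)
        np.testing.assert_array_equal(ff.counts[:, 0], expect)

    def test_amplitude_doubling_never_reduces_counts(self, rng):
        x = rng.normal(0.0, 5.0, (1, 120_000))
        pos = np.arange(2000, 118_000, 2500)
        for i in pos:
            x[0, i:i + 12] -= 60.0
        thr = np.array([-40.0])
        c1 = extract_features(x, FS, thresholds_uv=thr).counts.sum()
        c2 = extract_features(2 * x, FS, thresholds_uv=thr).counts.sum()
        assert c2 >= c1


class TestCalibration:
    def test_linear_model_recovered_within_five_percent(self, rng):
        n, d = 4000, 12
        H = rng.normal(1.0, 0.3, (d, 2))
        c = rng.uniform(5.0, 10.0, d)
        V = rng.normal(0.0, 0.5, (n, 2))
        X = V @ H.T + c + rng.normal(0.0, 0.01, (n, d))
        decoder = calibrate_kalman(X, V)
        np.testing.assert_allclose(decoder.H, H, rtol=0.05)
        np.testing.assert_allclose(decoder.c, c, rtol=0.05)

    def test_zero_variance_channel_is_excluded(self, rng):
        n = 4000
        V = rng.normal(0.0, 0.5, (n, 2))
        X = np.column_stack([V @ rng.normal(size=(2, 3)) + rng.normal(0, 0.1, (n, 3)),
                             np.full(n, 7.0)])
        decoder = calibrate_kalman(X, V)
        assert 3 not in decoder.kept_channels

    def test_calibration_is_deterministic(self, rng):
        user = make_synthetic_user(16, seed=3)
        a = calibrate_from_user(user, 60.0, seed=9)
        b = calibrate_from_user(user, 60.0, seed=9)
        np.testing.assert_array_equal(a.K, b.K)
        np.testing.assert_array_equal(a.H, b.H)

    def test_too_little_data_rejected(self, rng):
        with pytest.raises(ValueError, match="60"):
            calibrate_kalman(rng.normal(size=(100, 4)), rng.normal(size=(100, 2)))

    def test_degenerate_kinematics_rejected(self, rng):
        X = rng.normal(size=(4000, 4))
        V = np.zeros((4000, 2))
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_kalman(X, V)


@pytest.fixture(scope="module")
def user_and_decoder():
    user = make_synthetic_user(96, 10.0, 10.0, seed=5)
    return user, calibrate_from_user(user, 120.0, seed=5)


class TestDecode:
    def test_baseline_features_decode_to_near_zero_velocity(self, user_and_decoder):
        user, decoder = user_and_decoder
        rng = np.random.default_rng(6)
        decoder.reset()
        speeds = [np.hypot(*decoder.step(user.emit_counts(np.zeros(2), 0.02, rng)))
                  for _ in range(200)]
        assert np.mean(speeds[20:]) < 0.05 * user.v_norm * 5

    def test_pure_x_intent_decodes_toward_x(self, user_and_decoder):
        user, decoder = user_and_decoder
        rng = np.random.default_rng(7)
        decoder.reset()
        v_int = np.array([user.v_norm, 0.0])
        vs = np.array([decoder.step(user.emit_counts(v_int, 0.02, rng))
                       for _ in range(300)])
        mean_v = vs[50:].mean(axis=0)
        angle = np.degrees(np.arctan2(abs(mean_v[1]), mean_v[0]))
        assert angle < 15.0

    def test_larger_observation_noise_reduces_gain(self, user_and_decoder):
        user, decoder = user_and_decoder
        from bcilink.decoder import _steady_state_gain

        K2 = _steady_state_gain(decoder.A, decoder.W, decoder.H, 2 * decoder.R)
        noisy = KalmanDecoder(A=decoder.A, W=decoder.W, H=decoder.H, c=decoder.c,
                              R=2 * decoder.R, K=K2,
                              kept_channels=decoder.kept_channels)
        rng = np.random.default_rng(8)
        x = user.emit_counts(np.array([user.v_norm, 0.0]), 0.02, rng)
        decoder.reset()
        noisy.reset()
        v_a = decoder.step(x)
        v_b = noisy.step(x)
        assert np.hypot(*v_b) < np.hypot(*v_a)


class TestClick:
    def test_well_separated_classes_classified_almost_perfectly(self, rng):
        n = 2000
        a = rng.normal(0.0, 1.0, (n, 4))
        b = rng.normal(6.0, 1.0, (n, 4))  # d' ~ 6 per dimension
        X = np.vstack([a, b])
        y = np.r_[np.zeros(n), np.ones(n)]
        lda = train_click_classifier(X, y)
        acc = (classify_click(lda, X) == y).mean()
        assert acc > 0.99

    def test_identical_distributions_perform_at_chance(self, rng):
        X = rng.normal(size=(4000, 4))
        y = np.r_[np.zeros(2000), np.ones(2000)]
        lda = train_click_classifier(X, y)
        acc = (classify_click(lda, rng.normal(size=(4000, 4)))
               == np.r_[np.zeros(2000), np.ones(2000)]).mean()
        assert 0.45 < acc < 0.55

    def test_skewed_priors_with_uninformative_features_pick_majority(self, rng):
        X = rng.normal(size=(1000, 4))
        y = np.r_[np.zeros(900), np.ones(100)]
        lda = train_click_classifier(X, y)
        pred = classify_click(lda, rng.normal(size=(500, 4)))
        assert (pred == 0).mean() > 0.9

    def test_single_class_training_rejected(self, rng):
        with pytest.raises(ValueError, match="both"):
            train_click_classifier(rng.normal(size=(10, 2)), np.zeros(10))


class _PassthroughUser:
    """Noise-free 2-channel stand-in whose features are the intent itself."""

    v_norm = 0.4
    ramp = 0.12

    def intent(self, pos, target, rng):
        d = target - pos
        dist = float(np.hypot(*d))
        if dist < 1e-12:
            return np.zeros(2)
        return d / dist * self.v_norm * min(1.0, dist / self.ramp)

    def emit_counts(self, v, bin_s, rng):
        return np.asarray(v, dtype=float)


def _identity_decoder():
    eye = np.eye(2)
    return KalmanDecoder(A=np.zeros((2, 2)), W=eye, H=eye, c=np.zeros(2),
                         R=1e-12 * eye, K=eye, kept_channels=np.arange(2))


class TestGridTask:
    def test_oracle_decoder_acquires_every_target(self):
        result = run_grid_task(_identity_decoder(), _PassthroughUser(),
                               GridTaskConfig(), seed=1)
        m = performance_metrics(result)
        assert m["n_trials"] > 10
        assert m["percent_correct"] == 100.0
        assert m["mean_path_efficiency"] == pytest.approx(1.0, abs=0.01)
        assert m["mean_angle_error_deg"] == pytest.approx(0.0, abs=1.0)

    def test_zero_gain_decoder_times_out_every_trial(self):
        user = make_synthetic_user(8, seed=2)
        dead = KalmanDecoder(A=np.zeros((2, 2)), W=np.eye(2),
                             H=np.zeros((8, 2)), c=np.zeros(8),
                             R=np.eye(8), K=np.zeros((2, 8)),
                             kept_channels=np.arange(8))
        result = run_grid_task(dead, user, GridTaskConfig(block_s=40.0), seed=3)
        assert result.n_correct == 0
        assert all(t.outcome == "timeout" for t in result.trials)

    def test_angle_error_and_path_efficiency_ranges(self):
        user = make_synthetic_user(96, seed=4)
        decoder = calibrate_from_user(user, 60.0, seed=4)
        result = run_grid_task(decoder, user, GridTaskConfig(block_s=60.0), seed=4)
        m = performance_metrics(result)
        assert 0.0 <= m["mean_angle_error_deg"] <= 180.0
        assert 0.0 < m["mean_path_efficiency"] <= 1.0


class TestMetrics:
    def test_equal_correct_and_incorrect_floors_bitrate_at_zero(self):
        assert bitrate_bps(36, 5, 5, 120.0) == 0.0
        assert bitrate_bps(36, 3, 8, 120.0) == 0.0

    def test_grid_bitrate_arithmetic(self):
        assert bitrate_bps(36, 45, 0, 120.0) == pytest.approx(
            np.log2(35) * 45 / 120.0)
        assert bitrate_bps(36, 45, 0, 120.0) == pytest.approx(1.923, abs=5e-4)

    def test_bitrate_monotonicity(self):
        base = bitrate_bps(36, 20, 2, 120.0)
        assert bitrate_bps(36, 21, 2, 120.0) >= base
        assert bitrate_bps(36, 20, 3, 120.0) <= base
        assert bitrate_bps(36, 20, 2, 130.0) <= base

    def test_zero_elapsed_time_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            bitrate_bps(36, 1, 0, 0.0)

    def test_free_typing_rate(self):
        assert typing_rate_ccpm(196, 14.6) == pytest.approx(13.4, abs=0.05)
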