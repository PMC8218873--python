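"""Filtering, referencing, noise metrics, spike sorting and A/B comparison."""

import numpy as np
import pytest

from bcilink import fidelity
from bcilink.fidelity import (
    LFP_BAND,
    SPIKE_BAND,
    bandpass,
    common_average_reference,
    compare_catalogs,
    cross_system_noise,
    detect_threshold_crossings,
    residual_noise_rms,
    sort_units,
)

FS = 30_000.0


class TestBandpass:
    def test_dc_is_attenuated_by_more_than_40_db(self):
        x = np.full((1, 30_000), 100.0)
        y = bandpass(x, SPIKE_BAND, FS)
        assert np.sqrt(np.mean(y[0, 5000:-5000] ** 2)) < 100.0 * 1e-2

    @pytest.mark.parametrize("freq", [500.0, 1000.0, 4000.0])
    def test_in_band_sine_amplitude_preserved_within_1_db(self, freq):
        t = np.arange(60_000) / FS
        x = 50.0 * np.sin(2 * np.pi * freq * t)[None, :]
        y = bandpass(x, SPIKE_BAND, FS)[0, 10_000:-10_000]
        amp = np.sqrt(2) * np.sqrt(np.mean(y**2))
        assert 10 ** (-1 / 20) * 50.0 <= amp <= 10 ** (1 / 20) * 50.0

    def test_two_pass_commutes_with_time_reversal(self, rng):
        # zero-phase symmetry holds away from the edge transients
        x = rng.normal(size=(1, 60_000))
        a = bandpass(x[:, ::-1], SPIKE_BAND, FS)
        b = bandpass(x, SPIKE_BAND, FS)[:, ::-1]
        np.testing.assert_allclose(a[:, 5000:-5000], b[:, 5000:-5000], atol=1e-6)

    def test_two_pass_introduces_zero_phase_shift(self):
        t = np.arange(60_000) / FS
        x = np.sin(2 * np.pi * 1000.0 * t)[None, :]
        y = bandpass(x, SPIKE_BAND, FS)
        xc = np.correlate(y[0, 10_000:-10_000], x[0, 10_000:-10_000], "full")
        lag = int(np.argmax(xc)) - (xc.size // 2)
        assert lag == 0

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(np.zeros((1, 100)), (250.0, 20_000.0), FS)


class TestCommonAverageReference:
    def test_identical_channels_cancel_completely(self):
        x = np.tile(np.sin(np.arange(1000) / 7.0), (5, 1))
        y = common_average_reference(x, range(5))
        np.testing.assert_allclose(y, 0.0, atol=1e-12)

    def test_shared_artifact_removed_spikes_preserved(self, rng):
        t = np.arange(30_000) / FS
        artifact = 50.0 * np.sin(2 * np.pi * 60.0 * t)
        x = np.tile(artifact, (8, 1))
        spike = -80.0 * np.exp(-0.5 * ((np.arange(40) - 10) / 4.0) ** 2)
        x[0, 1000:1040] += spike
        y = common_average_reference(x, range(1, 8))  # subset excludes ch 0
        resid = y[1]  # artifact-only channel after CAR
        assert np.sqrt(np.mean(resid**2)) < np.sqrt(np.mean(artifact**2)) * 0.1
        assert y[0, 1000:1040].min() == pytest.approx(spike.min(), rel=0.05)

    def test_single_channel_subset_zeroes_that_channel(self, rng):
        x = rng.normal(size=(3, 100))
        y = common_average_reference(x, [1])
        np.testing.assert_allclose(y[1], 0.0, atol=1e-12)

    def test_subset_outside_recording_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            common_average_reference(np.zeros((2, 10)), [5])


class TestResidualNoise:
    def test_injected_sigma_recovered_within_two_percent(self):
        rng = np.random.default_rng(77)
        x = rng.normal(0.0, 6.5, (1, int(600 * FS)))
        report = residual_noise_rms(x, None, FS)
        assert report.rms_uv[0] == pytest.approx(6.5, rel=0.02)

    def test_zero_signal_reports_zero(self):
        report = residual_noise_rms(np.zeros((1, 1000)), None, FS)
        assert report.rms_uv[0] == 0.0

    def test_excision_removes_spike_contribution(self, rng):
        noise = rng.normal(0.0, 6.5, int(60 * FS))
        spikes = np.zeros_like(noise)
        events = np.arange(5000, noise.size - 5000, 9000)
        for i in events:
            spikes[i - 10:i + 20] = -120.0
        with_spikes = residual_noise_rms((noise + spikes)[None, :], [events], FS)
        alone = residual_noise_rms(noise[None, :], [events], FS)
        assert with_spikes.rms_uv[0] == pytest.approx(alone.rms_uv[0], rel=0.03)

    def test_everything_excised_reports_missing(self):
        report = residual_noise_rms(np.ones((1, 100)), [np.arange(0, 100, 10)],
                                    FS, excise_ms=1000.0)
        assert np.isnan(report.rms_uv[0])


class TestCrossSystemNoise:
    def test_identity_case_equals_own_metric(self, rng):
        x = rng.normal(0.0, 5.0, (4, 30_000))
        ref = x.mean(axis=0)
        a = cross_system_noise(x, ref, FS)
        b = cross_system_noise(x.copy(), ref, FS)
        np.testing.assert_allclose(a.rms_uv, b.rms_uv)

    def test_added_noise_inflates_by_variance_addition(self, rng):
        n = int(120 * FS)
        base = rng.normal(0.0, 4.0, (1, n))
        extra = rng.normal(0.0, 3.0, (1, n))
        ref = np.zeros(n)
        wired = cross_system_noise(base, ref, FS).rms_uv[0]
        wireless = cross_system_noise(base + extra, ref, FS).rms_uv[0]
        extra_band = cross_system_noise(extra, ref, FS).rms_uv[0]
        assert wireless == pytest.approx(np.hypot(wired, extra_band), rel=0.05)

    def test_constant_offset_matches_filter_response_oracle(self):
        n = 30_000
        x = np.full((1, n), 40.0)
        metric = cross_system_noise(x, np.zeros(n), FS).rms_uv[0]
        oracle = np.sqrt(np.mean(fidelity.bandpass(x, LFP_BAND, FS) ** 2))
        assert metric == pytest.approx(oracle)

    def test_misaligned_lengths_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            cross_system_noise(np.zeros((1, 10)), np.zeros(11), FS)


class TestThresholdCrossings:
    def test_all_zero_input_has_no_crossings(self):
        events = detect_threshold_crossings(np.zeros((2, 1000)), FS)
        assert all(e.size == 0 for e in events)

    def test_negative_pulses_detected_and_inverted_input_silent(self, rng):
        x = rng.normal(0.0, 5.0, int(10 * FS))
        pos = np.arange(3000, x.size - 3000, 6000)
        for i in pos:
            x[i:i + 20] -= 200.0
        thr = np.array([-50.0])
        (events,) = detect_threshold_crossings(x[None, :], FS, thresholds_uv=thr)
        assert events.size == pos.size
        (inv_events,) = detect_threshold_crossings(-x[None, :], FS,
                                                   thresholds_uv=thr)
        assert inv_events.size == 0

    def test_lockout_suppresses_refires(self):
        x = np.zeros(3000)
        x[100:110] = -100.0  # one 0.33 ms excursion, re-crossings within lockout
        x[112:118] = -100.0
        (events,) = detect_threshold_crossings(
            x[None, :], FS, thresholds_uv=np.array([-50.0]))
        assert events.size == 1


class TestSorting:
    def test_nss_channel_recovers_three_units_with_true_rates(self):
        from bcilink.signals import generate_spike_truth, nss_preset, synthesize_broadband

        config = nss_preset(n_channels=1, duration_s=300.0, seed=21)
        truth = generate_spike_truth(config)
        rec = synthesize_broadband(config, truth)
        f = bandpass(rec.data, SPIKE_BAND, rec.rate)
        events = detect_threshold_crossings(f, rec.rate)
        catalog = sort_units(f, events, rec.rate)
        assert len(catalog.units) == 3
        true_rates = sorted(t.spike_times.size / 300.0 for t in truth)
        for got, want in zip(sorted(catalog.rates), true_rates):
            assert got == pytest.approx(want, rel=0.05)

    def test_single_template_channel_yields_one_unit(self, rng):
        from bcilink.signals import SignalConfig, UnitSpec, biphasic_template
        from bcilink.signals import generate_spike_truth, synthesize_broadband

        tmpl = biphasic_template(120.0, 60_000.0)
        config = SignalConfig(
            n_channels=1, duration_s=60.0, white_noise_rms=5.0,
            units=(UnitSpec(0, 0, 5.0, tmpl),), seed=13,
        )
        truth = generate_spike_truth(config)
        rec = synthesize_broadband(config, truth)
        f = bandpass(rec.data, SPIKE_BAND, rec.rate)
        events = detect_threshold_crossings(f, rec.rate)
        catalog = sort_units(f, events, rec.rate)
        assert len(catalog.units) == 1

    def test_sparse_channel_is_skipped(self, rng):
        x = rng.normal(0.0, 5.0, (1, 30_000))
        catalog = sort_units(x, [np.array([100, 200])], FS)
        assert catalog.units == []


class TestCompareCatalogs:
    def test_catalog_against_itself_is_perfect(self, nss_small, bridged_small):
        from bcilink.pipeline import recover_unit_catalog

        cat = recover_unit_catalog(bridged_small.to_uv(), bridged_small.rate)
        cmp = compare_catalogs(cat, cat)
        matched = cmp[cmp["only_in"].isna()]
        assert len(matched) == len(cat.units)
        np.testing.assert_allclose(matched["correlation"], 1.0, atol=1e-12)
        np.testing.assert_allclose(matched["rate_diff"], 0.0)

    def test_missing_unit_reported_unmatched(self, bridged_small):
        from bcilink.pipeline import recover_unit_catalog

        cat = recover_unit_catalog(bridged_small.to_uv(), bridged_small.rate)
        import copy

        reduced = copy.deepcopy(cat)
        dropped = reduced.units.pop(0)
        cmp = compare_catalogs(cat, reduced)
        only_a = cmp[cmp["only_in"] == "a"]
        assert len(only_a) == 1
        assert only_a["rate_a"].iloc[0] == pytest.approx(dropped.rate_hz)
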