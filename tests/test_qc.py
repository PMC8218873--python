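"""Packet-drop accounting, SES, bit error rate, disruption timeline, spectra."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from bcilink.qc import (
    bit_error_rate,
    disruption_timeline,
    packet_drop_stats,
    segment_spectrogram,
    severely_errored_seconds,
)
from bcilink.receiver import CONCEALED, ReceiverLog
from bcilink.signals import BroadbandRecording


def _log(lost_mask, rate=20_000.0):
    status = np.where(np.asarray(lost_mask, bool), CONCEALED, 0).astype(np.int8)
    return ReceiverLog(status=status, frame_rate=rate)


class TestPacketDropStats:
    def test_zero_drops_report_zero_percent(self):
        report = packet_drop_stats(_log(np.zeros(10_000)))
        assert report.drop_pct == 0.0
        assert report.blocks_with_drops == 0

    def test_injected_drop_count_is_recovered_exactly(self, rng):
        lost = rng.random(50_000) < 0.01
        report = packet_drop_stats(_log(lost))
        assert report.dropped_frames == int(lost.sum())

    def test_469_drops_in_10000_frames_is_4_69_percent(self):
        lost = np.zeros(10_000, bool)
        lost[:469] = True
        report = packet_drop_stats(_log(lost))
        assert report.drop_pct == pytest.approx(4.69)

    def test_per_block_flags(self):
        lost = np.zeros(2000, bool)
        lost[1500] = True
        report = packet_drop_stats(_log(lost), [(0, 1000), (1000, 2000)])
        assert report.blocks_with_drops == 1
        assert report.per_block["drop_pct"].tolist() == [0.0, 0.1]

    def test_empty_log_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            packet_drop_stats(_log(np.zeros(0)))


class TestSes:
    def test_exactly_half_lost_is_counted(self):
        lost = np.zeros(20_000, bool)
        lost[:10_000] = True
        assert severely_errored_seconds(_log(lost)) == (1, 1.0)

    def test_just_under_half_is_not_counted(self):
        lost = np.zeros(20_000, bool)
        lost[:9_999] = True
        assert severely_errored_seconds(_log(lost)) == (0, 0.0)

    def test_partial_trailing_window_is_excluded(self):
        lost = np.ones(20_500, bool)
        assert severely_errored_seconds(_log(lost))[0] == 1

    @given(st.data())
    def test_matches_brute_force_window_scan(self, data):
        n = data.draw(st.integers(0, 3000))
        p = data.draw(st.floats(0.0, 1.0))
        seed = data.draw(st.integers(0, 2**31 - 1))
        lost = np.random.default_rng(seed).random(n) < p
        rate = 100.0
        count, secs = severely_errored_seconds(lost, rate)
        # oracle: explicit loop over non-overlapping windows from t=0
        w = int(rate)
        expect = sum(
            lost[i:i + w].sum() * 2 >= w
            for i in range(0, (n // w) * w, w)
        )
        assert count == expect and secs == float(expect)


class TestBitErrorRate:
    def test_identical_streams_have_zero_rate(self, rng):
        x = rng.integers(0, 2**15, (3, 1000))
        pooled, per_ch = bit_error_rate(x, x)
        assert pooled == 0.0 and np.all(per_ch == 0.0)

    def test_k_flipped_samples_of_n(self, rng):
        x = rng.integers(0, 2**15, (1, 1000))
        y = x.copy()
        y[0, :37] += 1
        pooled, _ = bit_error_rate(y, x)
        assert pooled == pytest.approx(37 / 1000)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            bit_error_rate(np.zeros((1, 5)), np.zeros((1, 6)))

    def test_excluded_epochs_are_ignored(self, rng):
        x = rng.integers(0, 2**15, (1, 100))
        y = x.copy()
        y[0, 10] += 1
        mask = np.zeros(100, bool)
        mask[10] = True
        pooled, _ = bit_error_rate(y, x, exclude_mask=mask)
        assert pooled == 0.0

    def test_per_bit_flips_convert_to_per_sample_rate(self, rng):
        # p per bit over 12 payload bits gives 1 - (1-p)^12 per sample
        from bcilink.link import ImpairmentConfig, LinkSpec, frame_stream, transmit

        spec = LinkSpec(n_channels=1)
        codes = np.full((1, 200_000), 2048, np.uint16)
        p = 5e-4
        (s,) = transmit(frame_stream(codes, spec),
                        ImpairmentConfig(bit_flip_prob=p, seed=8))
        pooled, _ = bit_error_rate(s.payloads.T, codes)
        q = 1 - (1 - p) ** 12
        lo, hi = stats.binom.interval(0.999, codes.size, q)
        assert lo / codes.size <= pooled <= hi / codes.size


class TestDisruptionTimeline:
    def test_24_hours_gives_288_segments(self):
        tl = disruption_timeline(24 * 3600.0)
        assert tl.n_segments == 288
        assert tl.n_disrupted == 0

    def test_35_disrupted_segments_are_175_minutes(self):
        gaps = [(i * 3600.0, i * 3600.0 + 300.0 * (35 // 7)) for i in range(7)]
        tl = disruption_timeline(24 * 3600.0, gaps=gaps)
        assert tl.n_disrupted == 35
        assert tl.disrupted_minutes == 175.0

    def test_cause_table_credits_annotated_segments(self):
        gaps = [(0.0, 600.0), (3000.0, 3300.0)]
        notes = [(0.0, 600.0, "caregiver activity")]
        tl = disruption_timeline(3600.0, gaps=gaps, annotations=notes)
        assert tl.cause_table["caregiver activity"] == 10.0
        assert tl.cause_table["unexplained"] == 5.0
        assert tl.cause_table.sum() == tl.disrupted_minutes

    def test_ses_in_log_marks_its_segment(self):
        lost = np.zeros(20_000 * 700, bool)
        lost[20_000 * 400: 20_000 * 401] = True  # one fully lost second at t=400
        tl = disruption_timeline(700.0, log=_log(lost))
        np.testing.assert_array_equal(tl.disrupted, [False, True, False])


class TestSegmentSpectrogram:
    def _tone_recording(self, freqs_amps, dur=300.0, fs=1000.0, noise=5.0, seed=0):
        t = np.arange(int(dur * fs)) / fs
        x = sum(a * np.sin(2 * np.pi * f * t) for f, a in freqs_amps)
        x = x + noise * np.random.default_rng(seed).standard_normal(t.size)
        return BroadbandRecording(x[None, :], fs)

    def test_single_tone_peak_within_one_bin(self):
        spectra = segment_spectrogram(self._tone_recording([(10.6, 20.0)]))
        assert spectra.peaks[0].size == 1
        assert abs(spectra.peaks[0][0] - 10.6) <= 0.25

    def test_two_tones_give_two_peaks(self):
        spectra = segment_spectrogram(
            self._tone_recording([(10.6, 20.0), (19.6, 12.0)]))
        assert spectra.peaks[0].size == 2
        assert abs(spectra.peaks[0][0] - 10.6) <= 0.25
        assert abs(spectra.peaks[0][1] - 19.6) <= 0.25

    def test_white_noise_has_no_peaks(self):
        spectra = segment_spectrogram(self._tone_recording([], noise=5.0))
        assert spectra.peaks[0].size == 0

    def test_parseval_total_power_within_one_percent(self):
        rec = self._tone_recording([(10.6, 20.0)], dur=300.0)
        spectra = segment_spectrogram(rec, fmax=None)
        total = np.trapezoid(spectra.psd[0], spectra.freqs)
        assert total == pytest.approx(rec.data[0].var(), rel=0.01)

    def test_disrupted_segments_are_masked(self):
        rec = self._tone_recording([(10.6, 20.0)], dur=600.0)
        spectra = segment_spectrogram(rec, disrupted=np.array([False, True]))
        assert np.isnan(spectra.psd[1]).all()
        assert spectra.peaks[1].size == 0

    def test_segment_shorter_than_window_rejected(self):
        rec = self._tone_recording([(10.6, 20.0)], dur=10.0)
        with pytest.raises(ValueError, match="shorter than the Welch window"):
            segment_spectrogram(rec, segment_s=2.0)
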