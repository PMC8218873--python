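"""Data-integrity statistics for wireless recordings.

Covers the link-quality accounting used to characterize in-home wireless
sessions: packet-drop rates per block, Severely Errored Seconds (any
non-overlapping 1-second window in which half or more of the samples were
lost), per-sample bit error rate against a known truth stream, 5-minute
disruption segmentation of long recordings, and segmentwise spectral
analysis (Welch periodograms with sub-0.25 Hz resolution at low frequency).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .receiver import ReceiverLog
from .signals import BroadbandRecording

__all__ = [
    "IntegrityReport",
    "DisruptionTimeline",
    "packet_drop_stats",
    "severely_errored_seconds",
    "bit_error_rate",
    "disruption_timeline",
    "segment_spectrogram",
    "SegmentSpectra",
]

SES_WINDOW_S = 1.0
SEGMENT_S = 300.0


@dataclass
class IntegrityReport:
    total_frames: int
    dropped_frames: int
    ses_count: int = 0
    total_seconds: float = 0.0
    per_block: pd.DataFrame | None = None

    @property
    def drop_pct(self) -> float:
        return 100.0 * self.dropped_frames / self.total_frames

    @property
    def ses_seconds(self) -> float:
        return self.ses_count * SES_WINDOW_S

    @property
    def blocks_with_drops(self) -> int:
        if self.per_block is None:
            return int(self.dropped_frames > 0)
        return int((self.per_block["dropped"] > 0).sum())

    def to_dict(self) -> dict:
        return {
            "total_frames": self.total_frames,
            "dropped_frames": self.dropped_frames,
            "drop_pct": self.drop_pct,
            "ses_count": self.ses_count,
            "ses_seconds": self.ses_seconds,
            "total_seconds": self.total_seconds,
            "blocks_with_drops": self.blocks_with_drops,
        }


def packet_drop_stats(log: ReceiverLog,
                      block_boundaries: list[tuple[int, int]] | None = None
                      ) -> IntegrityReport:
    """Drop counts and percentages, overall and per block of frames."""
    if log.n_frames == 0:
        raise ValueError("empty receiver log")
    lost = log.concealed_mask
    per_block = None
    if block_boundaries is not None:
        rows = []
        for b, (s, e) in enumerate(block_boundaries):
            d = int(lost[s:e].sum())
            rows.append((b, e - s, d, 100.0 * d / (e - s)))
        per_block = pd.DataFrame(rows, columns=["block", "frames", "dropped",
                                                "drop_pct"])
    report = IntegrityReport(
        total_frames=log.n_frames,
        dropped_frames=int(lost.sum()),
        total_seconds=log.n_frames / log.frame_rate,
        per_block=per_block,
    )
    report.ses_count, _ = severely_errored_seconds(log)
    return report


def severely_errored_seconds(log: ReceiverLog | np.ndarray,
                             rate: float | None = None) -> tuple[int, float]:
    """Count non-overlapping 1 s windows with >= 50% of frames lost.

    Windows tile the stream from t=0; a partial trailing window is excluded.
    Accepts a receiver log or a boolean lost-frame mask plus its frame rate.
    """
    if isinstance(log, ReceiverLog):
        lost = log.concealed_mask
        rate = log.frame_rate
    else:
        lost = np.asarray(log, dtype=bool)
        if rate is None:
            raise ValueError("rate is required when passing a raw lost mask")
    w = int(round(rate * SES_WINDOW_S))
    n_windows = lost.size // w
    if n_windows == 0:
        return 0, 0.0
    counts = lost[: n_windows * w].reshape(n_windows, w).sum(axis=1)
    ses = int((counts * 2 >= w).sum())  # "half or more"
    return ses, ses * SES_WINDOW_S


def bit_error_rate(received: np.ndarray, truth: np.ndarray,
                   exclude_mask: np.ndarray | None = None
                   ) -> tuple[float, np.ndarray]:
    """Fraction of samples whose digital value differs from the truth stream.

    ``exclude_mask`` (per sample, True = excluded) removes epochs attributed
    to concealed packet drops from the comparison.  Returns the pooled rate
    and the per-channel rates.
    """
    received = np.atleast_2d(np.asarray(received))
    truth = np.atleast_2d(np.asarray(truth))
    if received.shape != truth.shape:
        raise ValueError(f"shape mismatch: {received.shape} vs {truth.shape}")
    diff = received != truth
    if exclude_mask is not None:
        keep = ~np.asarray(exclude_mask, dtype=bool)
        diff = diff[:, keep]
    n = diff.shape[1]
    if n == 0:
        return float("nan"), np.full(received.shape[0], np.nan)
    return float(diff.mean()), diff.mean(axis=1)


@dataclass
class DisruptionTimeline:
    segment_s: float
    disrupted: np.ndarray  # (n_segments,) bool
    cause_table: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def n_segments(self) -> int:
        return self.disrupted.size

    @property
    def n_disrupted(self) -> int:
        return int(self.disrupted.sum())

    @property
    def disrupted_minutes(self) -> float:
        return self.n_disrupted * self.segment_s / 60.0


def disruption_timeline(duration_s: float,
                        log: ReceiverLog | None = None,
                        gaps: list[tuple[float, float]] | None = None,
                        annotations: list[tuple[float, float, str]] | None = None,
                        segment_s: float = SEGMENT_S) -> DisruptionTimeline:
    """Partition a long recording into 5-minute segments and mark disruptions.

    A segment is disrupted when it contains any Severely Errored Second (from
    the receiver log) or overlaps any unrecorded gap.  Annotations
    (start s, end s, label) build a cause table in minutes, crediting each
    disrupted segment to the label covering it (unlabelled disrupted
    segments are pooled under "unexplained").
    """
    n_seg = int(np.ceil(duration_s / segment_s))
    disrupted = np.zeros(n_seg, dtype=bool)
    if log is not None:
        lost = log.concealed_mask
        w = int(round(log.frame_rate * SES_WINDOW_S))
        n_windows = lost.size // w
        counts = lost[: n_windows * w].reshape(n_windows, w).sum(axis=1)
        ses_t = np.flatnonzero(counts * 2 >= w) * SES_WINDOW_S
        disrupted[np.minimum((ses_t / segment_s).astype(int), n_seg - 1)] = True
    for t0, t1 in gaps or []:
        s0 = int(t0 / segment_s)
        s1 = min(int(np.ceil(t1 / segment_s)), n_seg)
        disrupted[s0:max(s1, s0 + 1)] = True
    cause = {}
    if annotations:
        seg_cause = [None] * n_seg
        for t0, t1, label in annotations:
            s0 = int(t0 / segment_s)
            s1 = min(int(np.ceil(t1 / segment_s)), n_seg)
            for s in range(s0, max(s1, s0 + 1)):
                if disrupted[s] and seg_cause[s] is None:
                    seg_cause[s] = label
        for s in np.flatnonzero(disrupted):
            label = seg_cause[s] or "unexplained"
            cause[label] = cause.get(label, 0.0) + segment_s / 60.0
    return DisruptionTimeline(segment_s=segment_s, disrupted=disrupted,
                              cause_table=pd.Series(cause, dtype=float))


@dataclass
class SegmentSpectra:
    freqs: np.ndarray  # Hz
    psd: np.ndarray  # (n_segments, n_freqs), uV^2/Hz, NaN rows for masked segments
    segment_s: float
    peaks: list[np.ndarray]  # per segment: peak frequencies (Hz)


def segment_spectrogram(recording: BroadbandRecording,
                        segment_s: float = SEGMENT_S,
                        window_s: float = 4.0,
                        channel: int | None = None,
                        fmax: float | None = 250.0,
                        prominence_db: float = 6.0,
                        disrupted: np.ndarray | None = None) -> SegmentSpectra:
    """Welch PSD of contiguous segments with peak detection.

    4 s Hann windows with 50% overlap give 0.25 Hz resolution.  The PSD is
    averaged over channels unless one channel is requested.  Peaks are local
    maxima of the log-PSD with at least ``prominence_db`` prominence.
    Disrupted segments are masked (NaN PSD, no peaks).
    """
    fs = recording.rate
    nper = int(round(window_s * fs))
    seg_n = int(round(segment_s * fs))
    if seg_n < nper:
        raise ValueError("segment shorter than the Welch window")
    data = recording.data if channel is None else recording.data[channel:channel + 1]
    n_seg = data.shape[1] // seg_n
    if n_seg == 0:
        raise ValueError("recording shorter than one segment")
    psds = []
    freqs = None
    for s in range(n_seg):
        if disrupted is not None and disrupted[s]:
            psds.append(None)
            continue
        chunk = data[:, s * seg_n:(s + 1) * seg_n]
        freqs, p = sps.welch(chunk, fs=fs, nperseg=nper, noverlap=nper // 2,
                             detrend="constant", axis=1)
        psds.append(p.mean(axis=0))
    if freqs is None:
        raise ValueError("all segments are masked")
    if fmax is not None:
        keep = freqs <= fmax
        freqs = freqs[keep]
        psds = [None if p is None else p[keep] for p in psds]
    out = np.full((n_seg, freqs.size), np.nan)
    peaks: list[np.ndarray] = []
    for s, p in enumerate(psds):
        if p is None:
            peaks.append(np.empty(0))
            continue
        out[s] = p
        logp = 10 * np.log10(np.maximum(p, 1e-300))
        idx, _ = sps.find_peaks(logp, prominence=prominence_db)
        peaks.append(freqs[idx])
    return SegmentSpectra(freqs=freqs, psd=out, segment_s=segment_s, peaks=peaks)
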