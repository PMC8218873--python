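"""Wired-vs-wireless signal-fidelity analyses.

Band filtering (spike band 250 Hz – 7.5 kHz, LFP band 5 – 250 Hz, decode
band 250 Hz – 5 kHz two-pass zero-phase), common average referencing,
residual-RMS noise after spike excision, the between-system noise metric
(per-channel RMS relative to the wired multi-electrode mean), threshold
crossing detection, unsupervised template sorting, and catalog comparison.

The wired reference path models the cabled acquisition chain: 0.3 Hz –
7.5 kHz hardware filter, 30 kS/s, 16-bit samples at 0.25 uV/LSB.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signals import BroadbandRecording

__all__ = [
    "SPIKE_BAND",
    "LFP_BAND",
    "DECODE_BAND",
    "DISPLAY_LOWPASS_HZ",
    "bandpass",
    "common_average_reference",
    "residual_noise_rms",
    "cross_system_noise",
    "detect_threshold_crossings",
    "sort_units",
    "compare_catalogs",
    "UnitCatalog",
    "SortedUnit",
    "NoiseReport",
    "wired_path",
]

SPIKE_BAND = (250.0, 7500.0)
LFP_BAND = (5.0, 250.0)
DECODE_BAND = (250.0, 5000.0)
DISPLAY_LOWPASS_HZ = 100.0

WIRED_HW_BAND = (0.3, 7500.0)
WIRED_RATE = 30_000.0
WIRED_LSB_UV = 0.25

THRESHOLD_MULTIPLIER = -4.5
LOCKOUT_MS = 1.0
SNIPPET_PRE_MS = 0.5
SNIPPET_POST_MS = 1.1
MERGE_THRESHOLD = 0.9


def bandpass(data: np.ndarray, band: tuple[float, float], fs: float,
             mode: str = "two_pass", order: int = 4) -> np.ndarray:
    """Butterworth bandpass; ``two_pass`` applies it bidirectionally (zero phase)."""
    lo, hi = band
    if hi >= fs / 2:
        raise ValueError(f"band edge {hi} Hz at or above Nyquist ({fs / 2} Hz)")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    if mode == "two_pass":
        return sps.sosfiltfilt(sos, data, axis=-1)
    if mode == "causal":
        return sps.sosfilt(sos, data, axis=-1)
    raise ValueError(f"unknown mode {mode!r}")


def lowpass(data: np.ndarray, cutoff: float, fs: float, order: int = 4) -> np.ndarray:
    sos = sps.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, data, axis=-1)


def common_average_reference(data: np.ndarray, subset: np.ndarray | list[int]
                             ) -> np.ndarray:
    """Subtract the mean of the subset channels from every channel."""
    data = np.atleast_2d(np.asarray(data))
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("CAR subset must be non-empty")
    if subset.min() < 0 or subset.max() >= data.shape[0]:
        raise ValueError("CAR subset contains channels outside the recording")
    return data - data[subset].mean(axis=0, keepdims=True)


def car_subset_by_rms(data: np.ndarray, n: int = 32) -> np.ndarray:
    """Default subset rule: the n lowest-RMS channels."""
    rms = np.sqrt(np.mean(np.square(data), axis=1))
    return np.sort(np.argsort(rms)[:n])


@dataclass
class NoiseReport:
    """Per-channel residual RMS (uV) and its median."""

    rms_uv: np.ndarray  # (n_channels,), NaN where undefined
    band: tuple[float, float] | None = None

    @property
    def median_uv(self) -> float:
        return float(np.nanmedian(self.rms_uv))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"channel": np.arange(self.rms_uv.size),
                             "rms_uv": self.rms_uv})


def residual_noise_rms(filtered: np.ndarray,
                       spike_events: list[np.ndarray] | None,
                       fs: float, excise_ms: float = 0.8) -> NoiseReport:
    """RMS of the residual after excising +/- excise_ms around each spike."""
    x = np.atleast_2d(np.asarray(filtered))
    half = int(round(excise_ms * 1e-3 * fs))
    out = np.empty(x.shape[0])
    for ch in range(x.shape[0]):
        keep = np.ones(x.shape[1], dtype=bool)
        events = spike_events[ch] if spike_events is not None else np.empty(0, int)
        for i in np.asarray(events, dtype=int):
            keep[max(i - half, 0):i + half + 1] = False
        out[ch] = np.sqrt(np.mean(x[ch, keep] ** 2)) if keep.any() else np.nan
    return NoiseReport(rms_uv=out)


def cross_system_noise(data: np.ndarray, wired_reference_mean: np.ndarray,
                       fs: float, band: tuple[float, float] = LFP_BAND
                       ) -> NoiseReport:
    """Between-system metric: per-channel RMS of (channel - wired mean).

    The reference is the multi-electrode mean signal recorded in the wired
    condition; both are compared in the LFP band at a common sample rate.
    """
    data = np.atleast_2d(np.asarray(data))
    ref = np.asarray(wired_reference_mean)
    if ref.shape[-1] != data.shape[1]:
        raise ValueError("recording and wired reference lengths differ")
    resid = bandpass(data - ref[None, :], band, fs)
    return NoiseReport(rms_uv=np.sqrt(np.mean(resid ** 2, axis=1)), band=band)


def detect_threshold_crossings(filtered: np.ndarray, fs: float,
                               multiplier: float = THRESHOLD_MULTIPLIER,
                               lockout_ms: float = LOCKOUT_MS,
                               thresholds_uv: np.ndarray | None = None
                               ) -> list[np.ndarray]:
    """Negative threshold crossings at multiplier x per-channel noise RMS.

    The noise RMS is estimated robustly as ``median(|x|) / 0.6745`` so that
    the spikes themselves do not inflate the threshold.  Returns, per
    channel, the sample indices of crossings (first sample below threshold),
    with a lockout after each accepted event.
    """
    x = np.atleast_2d(np.asarray(filtered))
    lock = max(int(round(lockout_ms * 1e-3 * fs)), 1)
    events: list[np.ndarray] = []
    for ch in range(x.shape[0]):
        v = x[ch]
        thr = (thresholds_uv[ch] if thresholds_uv is not None
               else multiplier * np.median(np.abs(v)) / 0.6745)
        if thr >= 0:  # silent channel: RMS 0 -> no events
            events.append(np.empty(0, dtype=int))
            continue
        below = v < thr
        onsets = np.flatnonzero(below[1:] & ~below[:-1]) + 1
        if below[0]:
            onsets = np.insert(onsets, 0, 0)
        kept = []
        last = -lock - 1
        for i in onsets:
            if i - last > lock:
                kept.append(i)
                last = i
        events.append(np.asarray(kept, dtype=int))
    return events


@dataclass
class SortedUnit:
    channel: int
    unit_id: int
    waveform_mean: np.ndarray  # uV
    waveform_sd: np.ndarray
    spike_indices: np.ndarray  # sample indices (trough-aligned)
    rate_hz: float


@dataclass
class UnitCatalog:
    units: list[SortedUnit]
    fs: float
    duration_s: float

    def channel_units(self, channel: int) -> list[SortedUnit]:
        return [u for u in self.units if u.channel == channel]

    @property
    def rates(self) -> np.ndarray:
        return np.array([u.rate_hz for u in self.units])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(u.channel, u.unit_id, u.rate_hz, float(np.ptp(u.waveform_mean)),
              u.spike_indices.size) for u in self.units],
            columns=["channel", "unit_id", "rate_hz", "ptp_uv", "n_spikes"],
        )


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _extract_snippets(v: np.ndarray, events: np.ndarray, fs: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Trough-aligned snippets (-0.5 / +1.1 ms) around each crossing."""
    pre = int(round(SNIPPET_PRE_MS * 1e-3 * fs))
    post = int(round(SNIPPET_POST_MS * 1e-3 * fs))
    search = int(round(0.9e-3 * fs))  # trough search window after crossing
    snippets, centers = [], []
    for i in events:
        j = i + int(np.argmin(v[i:i + search + 1]))
        if j - pre < 0 or j + post > v.size:
            continue
        snippets.append(v[j - pre:j + post])
        centers.append(j)
    if not snippets:
        return np.empty((0, pre + post)), np.empty(0, dtype=int)
    return np.stack(snippets), np.asarray(centers, dtype=int)


def sort_units(filtered: np.ndarray, events: list[np.ndarray], fs: float,
               duration_s: float | None = None,
               merge_threshold: float = MERGE_THRESHOLD,
               min_events: int = 10,
               min_fraction: float = 0.02) -> UnitCatalog:
    """Unsupervised template sorting by correlation linkage.

    Deterministic: snippets are assigned to the first running template whose
    mean correlates above the merge threshold (templates are running means);
    templates are then agglomeratively merged at the same threshold, all
    snippets re-assigned to the nearest final template, and clusters smaller
    than ``min_events`` (or ``min_fraction`` of the channel's snippets —
    whichever is larger; isolated noise crossings never amount to more) are
    dropped.  Channels with fewer than ``min_events`` crossings are skipped.
    """
    x = np.atleast_2d(np.asarray(filtered))
    if duration_s is None:
        duration_s = x.shape[1] / fs
    units: list[SortedUnit] = []
    uid = 0
    for ch in range(x.shape[0]):
        ev = np.asarray(events[ch], dtype=int)
        if ev.size < min_events:
            continue
        snippets, centers = _extract_snippets(x[ch], ev, fs)
        if snippets.shape[0] < min_events:
            continue
        # leader pass
        sums: list[np.ndarray] = []
        counts: list[int] = []
        for s in snippets:
            best, best_c = -1, -2.0
            for t in range(len(sums)):
                c = _corr(sums[t] / counts[t], s)
                if c > best_c:
                    best, best_c = t, c
            if best >= 0 and best_c >= merge_threshold:
                sums[best] += s
                counts[best] += 1
            else:
                sums.append(s.astype(float).copy())
                counts.append(1)
        templates = [s / c for s, c in zip(sums, counts)]
        # agglomerative merge of templates
        merged = True
        while merged and len(templates) > 1:
            merged = False
            for a in range(len(templates)):
                for b in range(a + 1, len(templates)):
                    if _aligned_corr(templates[a], templates[b]) >= merge_threshold:
                        na, nb = counts[a], counts[b]
                        templates[a] = (templates[a] * na + templates[b] * nb) / (na + nb)
                        counts[a] = na + nb
                        del templates[b], counts[b]
                        merged = True
                        break
                if merged:
                    break
        # final assignment: nearest template in Euclidean (amplitude-aware)
        # distance — correlation alone confuses units of similar shape
        T = np.stack(templates)
        d2 = ((snippets[:, None, :] - T[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        floor = max(min_events, int(np.ceil(min_fraction * snippets.shape[0])))
        for t in range(len(templates)):
            members = assign == t
            if members.sum() < floor:
                continue
            w = snippets[members]
            units.append(SortedUnit(
                channel=ch, unit_id=uid,
                waveform_mean=w.mean(axis=0), waveform_sd=w.std(axis=0),
                spike_indices=centers[members],
                rate_hz=members.sum() / duration_s,
            ))
            uid += 1
    return UnitCatalog(units=units, fs=fs, duration_s=duration_s)


def _aligned_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Correlation after aligning waveform troughs."""
    ia, ib = int(np.argmin(a)), int(np.argmin(b))
    shift = ib - ia
    if shift > 0:
        a, b = a[:-shift or None], b[shift:]
    elif shift < 0:
        a, b = a[-shift:], b[:shift]
    n = min(len(a), len(b))
    return _corr(a[:n], b[:n])


def compare_catalogs(catalog_a: UnitCatalog, catalog_b: UnitCatalog
                     ) -> pd.DataFrame:
    """Greedy per-channel template matching by peak-aligned correlation.

    One row per matched pair (correlation, rates, rate difference) and one
    per unmatched unit (NaN correlation, side recorded in ``only_in``).
    """
    rows = []
    channels = sorted({u.channel for u in catalog_a.units}
                      | {u.channel for u in catalog_b.units})
    for ch in channels:
        ua = list(catalog_a.channel_units(ch))
        ub = list(catalog_b.channel_units(ch))
        pairs = sorted(
            ((_aligned_corr(x.waveform_mean, y.waveform_mean), i, j)
             for i, x in enumerate(ua) for j, y in enumerate(ub)),
            reverse=True,
        )
        used_a, used_b = set(), set()
        for c, i, j in pairs:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            rows.append((ch, c, ua[i].rate_hz, ub[j].rate_hz,
                         ub[j].rate_hz - ua[i].rate_hz, None))
        for i, x in enumerate(ua):
            if i not in used_a:
                rows.append((ch, np.nan, x.rate_hz, np.nan, np.nan, "a"))
        for j, y in enumerate(ub):
            if j not in used_b:
                rows.append((ch, np.nan, np.nan, y.rate_hz, np.nan, "b"))
    return pd.DataFrame(rows, columns=["channel", "correlation", "rate_a",
                                       "rate_b", "rate_diff", "only_in"])


def wired_path(recording: BroadbandRecording,
               rate: float = WIRED_RATE, lsb_uv: float = WIRED_LSB_UV
               ) -> BroadbandRecording:
    """Cabled reference chain: 0.3 Hz - 7.5 kHz filter, 30 kS/s, 16-bit.

    Returns the recording as acquired by the wired system, in uV (already
    quantized to the 16-bit grid).
    """
    sos = sps.butter(4, WIRED_HW_BAND, btype="bandpass", fs=recording.rate,
                     output="sos")
    x = sps.sosfiltfilt(sos, recording.data, axis=1)
    ratio = Fraction(int(round(rate)), int(round(recording.rate)))
    if ratio != 1:
        x = sps.resample_poly(x, ratio.numerator, ratio.denominator, axis=1)
    q = np.clip(np.round(x / lsb_uv), -32768, 32767)
    return BroadbandRecording(data=q * lsb_uv, rate=rate,
                              channel_ids=recording.channel_ids,
                              truth=recording.truth)
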