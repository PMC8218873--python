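"""Bit-error detection and repair on the reconstructed 30 kS/s stream.

A most-significant-bit flip produces a biologically implausible voltage
discontinuity: the detection rule flags any voltage shift of 500 uV or
greater between consecutive 33 us samples (a 15 uV/us slew rate).  A
corrupted value lasts one sample — or two when a sample-and-hold upsample
repeat follows — then returns to baseline, so both the outgoing and the
returning step exceed the threshold and both edges of the glitch are
flagged.  Repair replaces each flagged sample with the most recent
unflagged sample on that electrode.  Recurring flags on one channel within
a short window are classified as a "digital noise" epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MitigationConfig",
    "FlagTrack",
    "detect_msb_flips",
    "repair",
    "mitigate",
    "detect_digital_noise",
    "find_upsample_repeats",
    "RepeatReport",
]


@dataclass(frozen=True)
class MitigationConfig:
    step_threshold_uv: float = 500.0  # per single sample
    sample_rate: float = 30_000.0
    digital_noise_min_events: int = 3
    digital_noise_window_ms: float = 300.0

    def __post_init__(self) -> None:
        if self.step_threshold_uv <= 0 or self.digital_noise_window_ms <= 0:
            raise ValueError("thresholds and windows must be > 0")

    @property
    def slew_rate_uv_per_us(self) -> float:
        """The single-sample step expressed as a slew rate (uV/us)."""
        return self.step_threshold_uv / (1e6 / self.sample_rate)


@dataclass
class FlagTrack:
    """Per-channel flagged sample indices with pre/post voltages."""

    flags: dict[int, np.ndarray]  # channel -> sorted sample indices
    pre_values: dict[int, np.ndarray]  # voltage at flag - 1 (uV)
    post_values: dict[int, np.ndarray]  # voltage at the flag (uV)
    n_samples: int
    config: MitigationConfig = field(default_factory=MitigationConfig)

    @property
    def n_flags(self) -> int:
        return sum(v.size for v in self.flags.values())

    def channel_flags(self, channel: int) -> np.ndarray:
        return self.flags.get(channel, np.empty(0, dtype=int))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (ch, int(i), float(pre), float(post))
            for ch, idx in sorted(self.flags.items())
            for i, pre, post in zip(idx, self.pre_values[ch], self.post_values[ch])
        ]
        return pd.DataFrame(rows, columns=["channel", "sample_index",
                                           "pre_value", "post_value"])


def detect_msb_flips(stream_uv: np.ndarray,
                     config: MitigationConfig | None = None) -> FlagTrack:
    """Flag samples whose step from the previous sample is >= the threshold.

    The comparison is inclusive ("500 uV or greater").  A flagged sample
    followed by an exact repeat of itself (the upsample-repeat case) flags
    the repeat as well.
    """
    config = config or MitigationConfig()
    x = np.atleast_2d(np.asarray(stream_uv, dtype=np.float64))
    thr = config.step_threshold_uv
    flags: dict[int, np.ndarray] = {}
    pre: dict[int, np.ndarray] = {}
    post: dict[int, np.ndarray] = {}
    for ch in range(x.shape[0]):
        v = x[ch]
        cand = np.flatnonzero(np.abs(np.diff(v)) >= thr) + 1
        hit = np.zeros(v.size, dtype=bool)
        baseline = 0.0  # last good value before the open corruption run
        for i in cand:
            if hit[i - 1] and abs(v[i] - baseline) < thr:
                continue  # the single-step return to baseline, not a new error
            if not hit[i - 1]:
                baseline = v[i - 1]
            hit[i] = True
            # a corrupted value may persist through an upsample repeat
            j = i + 1
            while j < v.size and v[j] == v[i]:
                hit[j] = True
                j += 1
        idx = np.flatnonzero(hit)
        if idx.size:
            flags[ch] = idx
            pre[ch] = v[np.maximum(idx - 1, 0)]
            post[ch] = v[idx]
    return FlagTrack(flags=flags, pre_values=pre, post_values=post,
                     n_samples=x.shape[1], config=config)


def repair(stream_uv: np.ndarray, track: FlagTrack) -> np.ndarray:
    """Replace each flagged sample with its preceding good sample.

    Applied in index order, so a run of flags propagates the last good
    value.  A flag at index 0 has no predecessor and is set to 0 uV
    (mid-scale).
    """
    x = np.atleast_2d(np.array(stream_uv, dtype=np.float64, copy=True))
    for ch, idx in track.flags.items():
        v = x[ch]
        flagged = np.zeros(v.size, dtype=bool)
        flagged[idx] = True
        good = np.where(flagged, -1, np.arange(v.size))
        np.maximum.accumulate(good, out=good)
        lead = good < 0
        src = good.copy()
        src[lead] = 0
        v[:] = v[src]
        v[lead] = 0.0
    return x.reshape(np.shape(stream_uv))


def mitigate(stream_uv: np.ndarray,
             config: MitigationConfig | None = None) -> tuple[np.ndarray, FlagTrack]:
    """Detect and repair in one pass (the real-time configuration)."""
    track = detect_msb_flips(stream_uv, config)
    return repair(stream_uv, track), track


def detect_digital_noise(track: FlagTrack,
                         config: MitigationConfig | None = None
                         ) -> dict[int, list[tuple[int, int]]]:
    """Per-channel epochs of recurring flags.

    An epoch opens when at least ``digital_noise_min_events`` flags fall
    within ``digital_noise_window_ms`` on one channel; it spans the first to
    the last contributing flag.  Overlapping or touching epochs are merged.
    """
    config = config or track.config
    w = int(round(config.digital_noise_window_ms * 1e-3 * config.sample_rate))
    k = config.digital_noise_min_events
    epochs: dict[int, list[tuple[int, int]]] = {}
    for ch, idx in track.flags.items():
        if idx.size < k:
            continue
        spans: list[tuple[int, int]] = []
        # window of k consecutive flags fitting inside w samples
        for i in range(idx.size - k + 1):
            if idx[i + k - 1] - idx[i] <= w:
                spans.append((int(idx[i]), int(idx[i + k - 1])))
        if not spans:
            continue
        merged = [spans[0]]
        for s, e in spans[1:]:
            ps, pe = merged[-1]
            if s <= pe:
                merged[-1] = (ps, max(pe, e))
            else:
                merged.append((s, e))
        epochs[ch] = merged
    return epochs


@dataclass
class RepeatReport:
    """All-channel repeat frames found in a 30 kS/s stream."""

    repeat_mask: np.ndarray  # (M,) output frame equals its predecessor on all channels
    periodic_mask: np.ndarray  # repeats in the expected sample-and-hold phase
    aperiodic_mask: np.ndarray  # off-phase repeats: candidate concealed drops

    @property
    def n_repeats(self) -> int:
        return int(self.repeat_mask.sum())


def find_upsample_repeats(stream: np.ndarray, phase: int = 1) -> RepeatReport:
    """Mark output frames identical to their predecessor across all channels.

    The sample-and-hold conversion leaves a repeat at every output index
    with ``j % 3 == phase`` (phase 1 when both clocks start at t=0); repeats
    off that phase indicate aperiodic events such as concealed frame drops.
    """
    x = np.atleast_2d(np.asarray(stream))
    m = x.shape[1]
    rep = np.zeros(m, dtype=bool)
    rep[1:] = np.all(x[:, 1:] == x[:, :-1], axis=0)
    j = np.arange(m)
    in_phase = (j % 3) == phase
    return RepeatReport(
        repeat_mask=rep,
        periodic_mask=rep & in_phase,
        aperiodic_mask=rep & ~in_phase,
    )
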