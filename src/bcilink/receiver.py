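"""Receiver / digital-hub chain: antenna selection, concealment, upsampling.

A frame is valid when any antenna recovered it (the lowest antenna index
wins).  When no antenna recovered a frame, the previous valid frame's codes
are re-inserted on all channels ("concealment"); a drop before any valid
frame yields mid-scale codes.  The 20 kS/s stream is then upsampled to
30 kS/s by sample-and-hold — a 30 kHz clock reads a register updated at
20 kHz, so each consecutive input pair (s1, s2) emits (s1, s1, s2) — and
each 12-bit code is up-shifted by four bits into a 16-bit sample (LSB
0.25 uV after the shift).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .link import AntennaStream, CodeStream12, LinkSpec

__all__ = [
    "ReceiverLog",
    "BridgeOutput",
    "select_and_conceal",
    "upsample_30k",
    "upshift_16",
    "bridge",
    "CONCEALED",
]

CONCEALED = -1  # status value marking a concealed (all-antennas-lost) frame
UPSHIFT_BITS = 4
OUTPUT_RATE_FACTOR = (3, 2)  # 20 kS/s -> 30 kS/s


@dataclass
class ReceiverLog:
    """Per-frame disposition: antenna index that supplied it, or CONCEALED."""

    status: np.ndarray  # (n_frames,) int8: antenna id >= 0, or CONCEALED
    frame_rate: float

    @property
    def n_frames(self) -> int:
        return self.status.size

    @property
    def concealed_mask(self) -> np.ndarray:
        return self.status == CONCEALED

    @property
    def n_concealed(self) -> int:
        return int(self.concealed_mask.sum())

    @property
    def n_valid(self) -> int:
        return self.n_frames - self.n_concealed

    def to_dict(self) -> dict:
        return {
            "n_frames": self.n_frames,
            "n_valid": self.n_valid,
            "n_concealed": self.n_concealed,
            "frame_rate": self.frame_rate,
            "concealed_indices": np.flatnonzero(self.concealed_mask).tolist(),
        }


@dataclass
class BridgeOutput:
    """The reconstructed 30 kS/s, 16-bit stream."""

    stream: np.ndarray  # (n_channels, M) int16, signed, multiples of 16 when clean
    repeat_mask: np.ndarray  # (M,) bool: sample is an upsample repeat
    receiver_log: ReceiverLog
    rate: float  # output sample rate, 30 kS/s
    lsb_uv: float  # uV per 16-bit step (0.25 with the default ADC scale)

    def to_uv(self) -> np.ndarray:
        return self.stream.astype(np.float64) * self.lsb_uv


def select_and_conceal(streams: list[AntennaStream]) -> tuple[CodeStream12, ReceiverLog]:
    """Merge antennas and conceal frames lost on all of them."""
    if not streams:
        raise ValueError("at least one antenna stream is required")
    n = streams[0].n_frames
    if any(s.n_frames != n for s in streams):
        raise ValueError("antenna streams must have equal frame counts")
    spec = streams[0].spec
    recovered = np.stack([s.recovered for s in streams])  # (A, n)
    any_rec = recovered.any(axis=0)
    chosen = np.where(any_rec, recovered.argmax(axis=0), CONCEALED).astype(np.int8)

    if any_rec.all() and len(streams) == 1:
        out = streams[0].payloads  # fast path: nothing to merge or conceal
    else:
        out = np.empty_like(streams[0].payloads)
        for a, s in enumerate(streams):
            m = chosen == a
            if m.any():
                out[m] = s.payloads[m]
        if not any_rec.all():
            # forward-fill: each concealed frame repeats the last valid frame
            idx = np.where(any_rec, np.arange(n), -1)
            np.maximum.accumulate(idx, out=idx)
            lead = idx < 0
            filled = idx.copy()
            filled[lead] = 0
            out = out[filled]
            out[lead] = spec.midscale
    log = ReceiverLog(status=chosen, frame_rate=spec.adc_rate)
    return CodeStream12(codes=np.ascontiguousarray(out.T), spec=spec), log


def upsample_30k(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sample-and-hold 20 kS/s -> 30 kS/s along the last axis.

    With both clocks starting at t=0, output sample j reads input sample
    floor(2j/3); every third output (j % 3 == 1) is a repeat of its
    predecessor.  Output length is ceil(3n/2).
    """
    codes = np.asarray(codes)
    n = codes.shape[-1]
    m = -(-3 * n // 2)
    j = np.arange(m)
    src = (2 * j) // 3
    out = codes[..., src]
    mask = np.zeros(m, dtype=bool)
    mask[1:] = src[1:] == src[:-1]
    return out, mask


def upshift_16(codes: np.ndarray, spec: LinkSpec | None = None,
               signed: bool = True) -> np.ndarray:
    """Four-bit up-shift of 12-bit codes into 16-bit samples.

    ``signed=False`` returns the raw offset-binary 16-bit value
    (code x 16); the default re-centers to a signed int16 so that
    mid-scale maps to 0 (i.e. 0 uV under the ADC convention).
    """
    spec = spec or LinkSpec()
    codes = np.asarray(codes)
    if codes.min(initial=0) < 0 or codes.max(initial=0) >= spec.n_codes:
        raise ValueError("codes out of 12-bit range")
    if not signed:
        return (codes.astype(np.uint16)) << UPSHIFT_BITS
    return ((codes.astype(np.int32) - spec.midscale) << UPSHIFT_BITS).astype(np.int16)


def bridge(streams: list[AntennaStream],
           repeat_corrupt_prob: float = 0.0, seed: int = 0) -> BridgeOutput:
    """Full receiver chain: select/conceal -> sample-and-hold -> up-shift.

    ``repeat_corrupt_prob`` optionally flips one random payload bit in that
    fraction of upsample-repeat samples (per channel), reproducing the
    observed artifact class in which a repeat frame occasionally differs
    from the value it should duplicate.  Off by default.
    """
    codes20, log = select_and_conceal(streams)
    spec = codes20.spec
    codes30, mask = upsample_30k(codes20.codes)
    if repeat_corrupt_prob > 0:
        rng = np.random.default_rng([seed, 29])
        rep_idx = np.flatnonzero(mask)
        n_ch = codes30.shape[0]
        hit = rng.random((n_ch, rep_idx.size)) < repeat_corrupt_prob
        bits = rng.integers(0, spec.adc_bits, size=hit.sum())
        ch_i, rep_i = np.nonzero(hit)
        codes30 = codes30.copy()
        codes30[ch_i, rep_idx[rep_i]] ^= (np.uint16(1) << bits).astype(np.uint16)
    stream = upshift_16(codes30, spec)
    return BridgeOutput(
        stream=stream,
        repeat_mask=mask,
        receiver_log=log,
        rate=spec.adc_rate * OUTPUT_RATE_FACTOR[0] / OUTPUT_RATE_FACTOR[1],
        lsb_uv=spec.adc_lsb_uv / (1 << UPSHIFT_BITS),
    )
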