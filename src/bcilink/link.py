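"""Digitization, framing, Manchester line coding and wireless impairments.

The transmitter band-limits each electrode (1 Hz – 7.8 kHz hardware filter),
digitizes at 20 kS/s with 12 bits per sample, and emits one frame every
50 us: a 24-bit sync word followed by one 12-bit code from each of the 96
electrodes (1176 bits per frame, 23.04 Mbit/s raw, doubled on the line by
Manchester encoding).  Transmission to each antenna is impaired by frame
(sync) loss — Bernoulli or bursty Gilbert–Elliott — and by independent
payload bit flips.

ADC convention: offset binary, LSB 4 uV, 0 uV at mid-scale code 2048,
saturating at codes 0 / 4095.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .signals import BroadbandRecording

__all__ = [
    "LinkSpec",
    "CodeStream12",
    "FrameStream",
    "ImpairmentConfig",
    "AntennaStream",
    "adc_digitize",
    "frame_stream",
    "deframe",
    "manchester_encode",
    "manchester_decode",
    "transmit",
]

SYNC_WORD_DEFAULT = 0xB4D5A3


@dataclass(frozen=True)
class LinkSpec:
    adc_rate: float = 20_000.0  # S/s per electrode
    adc_bits: int = 12
    sync_bits: int = 24
    sync_word: int = SYNC_WORD_DEFAULT
    n_channels: int = 96
    hw_highpass: float = 1.0  # Hz
    hw_lowpass: float = 7_800.0  # Hz
    adc_lsb_uv: float = 4.0

    def __post_init__(self) -> None:
        if not 0 <= self.sync_word < 2**self.sync_bits:
            raise ValueError("sync word does not fit in sync_bits")

    @property
    def frame_period_s(self) -> float:
        return 1.0 / self.adc_rate  # 50 us at the default rate

    @property
    def n_codes(self) -> int:
        return 2**self.adc_bits

    @property
    def midscale(self) -> int:
        return self.n_codes // 2

    @property
    def fullscale_uv(self) -> float:
        """Largest representable positive voltage (code n_codes - 1)."""
        return (self.n_codes - 1 - self.midscale) * self.adc_lsb_uv

    @property
    def frame_bits(self) -> int:
        return self.sync_bits + self.n_channels * self.adc_bits

    @property
    def data_rate_bps(self) -> float:
        """Raw payload data rate: channels x sample rate x bits per sample."""
        return self.n_channels * self.adc_rate * self.adc_bits

    def uv_to_code(self, uv: np.ndarray) -> np.ndarray:
        code = np.round(np.asarray(uv) / self.adc_lsb_uv).astype(np.int64)
        code += self.midscale
        return np.clip(code, 0, self.n_codes - 1).astype(np.uint16)

    def code_to_uv(self, code: np.ndarray) -> np.ndarray:
        return (np.asarray(code).astype(np.int64) - self.midscale) * self.adc_lsb_uv


@dataclass
class CodeStream12:
    """12-bit ADC output: (n_channels, n_samples) codes at adc_rate."""

    codes: np.ndarray  # uint16, values in [0, 4095]
    spec: LinkSpec

    @property
    def n_samples(self) -> int:
        return self.codes.shape[1]

    def to_uv(self) -> np.ndarray:
        return self.spec.code_to_uv(self.codes)


@dataclass
class FrameStream:
    """One frame per ADC tick: payloads[i] holds the 96 codes of frame i."""

    payloads: np.ndarray  # (n_frames, n_channels) uint16
    spec: LinkSpec

    @property
    def n_frames(self) -> int:
        return self.payloads.shape[0]

    def serialize_frame(self, i: int) -> np.ndarray:
        """Bit vector of frame i: sync word then n_channels 12-bit codes, MSB first."""
        s = self.spec
        bits = np.empty(s.frame_bits, dtype=np.uint8)
        sync = np.array([(s.sync_word >> k) & 1 for k in range(s.sync_bits - 1, -1, -1)],
                        dtype=np.uint8)
        bits[: s.sync_bits] = sync
        payload = self.payloads[i].astype(np.uint16)
        shifts = np.arange(s.adc_bits - 1, -1, -1)
        bits[s.sync_bits:] = ((payload[:, None] >> shifts[None, :]) & 1).reshape(-1)
        return bits

    def to_bits(self) -> np.ndarray:
        return np.concatenate([self.serialize_frame(i) for i in range(self.n_frames)])


def adc_digitize(recording: BroadbandRecording, spec: LinkSpec | None = None) -> CodeStream12:
    """Band-limit, resample to the ADC rate and quantize to 12-bit codes.

    The hardware filter is modeled as a 4th-order Butterworth bandpass
    applied zero-phase; resampling uses a polyphase rational converter.
    """
    spec = spec or LinkSpec()
    if recording.rate < 2 * spec.hw_lowpass:
        raise ValueError("recording rate must be >= 2x the hardware lowpass")
    if recording.duration_s < spec.frame_period_s:
        raise ValueError("recording shorter than one frame period")
    sos = sps.butter(4, [spec.hw_highpass, spec.hw_lowpass], btype="bandpass",
                     fs=recording.rate, output="sos")
    filtered = sps.sosfiltfilt(sos, recording.data, axis=1)
    ratio = Fraction(int(round(spec.adc_rate)), int(round(recording.rate)))
    if ratio != 1:
        filtered = sps.resample_poly(filtered, ratio.numerator, ratio.denominator, axis=1)
    return CodeStream12(codes=spec.uv_to_code(filtered), spec=spec)


def frame_stream(codes: CodeStream12 | np.ndarray, spec: LinkSpec | None = None) -> FrameStream:
    if isinstance(codes, CodeStream12):
        spec = spec or codes.spec
        codes = codes.codes
    spec = spec or LinkSpec()
    codes = np.asarray(codes)
    if codes.shape[0] != spec.n_channels:
        raise ValueError(
            f"expected {spec.n_channels} channels, got {codes.shape[0]} "
            "(override LinkSpec.n_channels to frame other layouts)"
        )
    if codes.max(initial=0) >= spec.n_codes:
        raise ValueError("codes exceed the ADC range")
    return FrameStream(payloads=np.ascontiguousarray(codes.T), spec=spec)


def deframe(frames: FrameStream) -> CodeStream12:
    return CodeStream12(codes=np.ascontiguousarray(frames.payloads.T), spec=frames.spec)


def frames_from_bits(bits: np.ndarray, spec: LinkSpec | None = None) -> FrameStream:
    """Parse a serialized bit stream back into frames.

    The stream must be an integer number of frames; every frame must open
    with the expected sync word.
    """
    spec = spec or LinkSpec()
    bits = np.asarray(bits, dtype=np.uint8)
    if bits.size % spec.frame_bits:
        raise ValueError("bit stream is not an integer number of frames")
    n = bits.size // spec.frame_bits
    per_frame = bits.reshape(n, spec.frame_bits)
    sync = np.array([(spec.sync_word >> k) & 1 for k in range(spec.sync_bits - 1, -1, -1)],
                    dtype=np.uint8)
    if not np.array_equal(per_frame[:, : spec.sync_bits],
                          np.broadcast_to(sync, (n, spec.sync_bits))):
        raise ValueError("sync word mismatch while parsing the bit stream")
    payload_bits = per_frame[:, spec.sync_bits:].reshape(n, spec.n_channels, spec.adc_bits)
    weights = (1 << np.arange(spec.adc_bits - 1, -1, -1)).astype(np.uint16)
    payloads = (payload_bits * weights).sum(axis=2).astype(np.uint16)
    return FrameStream(payloads=payloads, spec=spec)


def manchester_encode(bits: np.ndarray) -> np.ndarray:
    """IEEE convention: data 0 -> line (1, 0); data 1 -> line (0, 1)."""
    bits = np.asarray(bits, dtype=np.uint8)
    line = np.empty(2 * bits.size, dtype=np.uint8)
    line[0::2] = 1 - bits
    line[1::2] = bits
    return line


def manchester_decode(line: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Invert the line code.

    Returns ``(bits, symbol_error)``: an invalid pair (00 or 11) carries no
    transition and is flagged in ``symbol_error``; its decoded bit is 0.
    """
    line = np.asarray(line, dtype=np.uint8)
    if line.size % 2:
        raise ValueError("Manchester line stream must have even length")
    first, second = line[0::2], line[1::2]
    errors = first == second
    bits = np.where(errors, 0, second).astype(np.uint8)
    return bits, errors


@dataclass(frozen=True)
class GilbertElliott:
    """Two-state burst loss model: good/bad states with per-state drop rates."""

    p_good_to_bad: float
    p_bad_to_good: float
    drop_good: float = 0.0
    drop_bad: float = 1.0

    def __post_init__(self) -> None:
        for p in (self.p_good_to_bad, self.p_bad_to_good, self.drop_good, self.drop_bad):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")

    def sample_drops(self, n: int, rng: np.random.Generator) -> np.ndarray:
        state = np.empty(n, dtype=bool)  # True = bad
        u = rng.random(n)
        # stationary start
        denom = self.p_good_to_bad + self.p_bad_to_good
        pi_bad = self.p_good_to_bad / denom if denom > 0 else 0.0
        cur = u[0] < pi_bad if n else False
        for i in range(n):
            if i:
                cur = (u[i] < self.p_good_to_bad) if not cur else (u[i] >= self.p_bad_to_good)
            state[i] = cur
        v = rng.random(n)
        return np.where(state, v < self.drop_bad, v < self.drop_good)


@dataclass(frozen=True)
class ImpairmentConfig:
    drop_prob: float = 0.0  # Bernoulli sync-loss probability per frame
    gilbert_elliott: GilbertElliott | None = None  # overrides drop_prob if set
    bit_flip_prob: float = 0.0  # per payload bit, recovered frames only
    n_antennas: int = 1
    per_antenna_independent: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.drop_prob <= 1 or not 0 <= self.bit_flip_prob <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_antennas < 1:
            raise ValueError("n_antennas must be >= 1")


@dataclass
class AntennaStream:
    """Frames as received by one antenna."""

    antenna_id: int
    payloads: np.ndarray  # (n_frames, n_channels); content of lost frames is unusable
    recovered: np.ndarray  # (n_frames,) bool; False = sync lost
    spec: LinkSpec

    @property
    def n_frames(self) -> int:
        return self.recovered.size


def _apply_bit_flips(payloads: np.ndarray, recovered: np.ndarray, p: float,
                     bits: int, rng: np.random.Generator) -> np.ndarray:
    """Flip each payload bit of recovered frames independently with prob p."""
    out = payloads.copy()
    rec_idx = np.flatnonzero(recovered)
    n_bits = rec_idx.size * payloads.shape[1] * bits
    if n_bits == 0 or p == 0:
        return out
    k = rng.binomial(n_bits, p)
    if k == 0:
        return out
    flat = rng.choice(n_bits, size=k, replace=False)
    per_frame = payloads.shape[1] * bits
    fi = rec_idx[flat // per_frame]
    rem = flat % per_frame
    ci = rem // bits
    bi = rem % bits
    np.bitwise_xor.at(out, (fi, ci), (np.uint16(1) << bi.astype(np.uint16)))
    return out


def transmit(frames: FrameStream, impairment: ImpairmentConfig | None = None
             ) -> list[AntennaStream]:
    """Simulate reception of the frame stream on each antenna.

    Per antenna (independent draws unless configured otherwise): sync loss
    from the drop model, then independent payload bit flips on recovered
    frames.  With zero impairment the payload array is shared, not copied.
    """
    impairment = impairment or ImpairmentConfig()
    n = frames.n_frames
    streams: list[AntennaStream] = []
    shared_drop = None
    for a in range(impairment.n_antennas):
        stream_seed = a if impairment.per_antenna_independent else 0
        rng = np.random.default_rng([impairment.seed, 7, stream_seed])
        if impairment.per_antenna_independent or shared_drop is None:
            if impairment.gilbert_elliott is not None:
                drops = impairment.gilbert_elliott.sample_drops(n, rng)
            elif impairment.drop_prob > 0:
                drops = rng.random(n) < impairment.drop_prob
            else:
                drops = np.zeros(n, dtype=bool)
            shared_drop = drops
        else:
            drops = shared_drop
        recovered = ~drops
        if impairment.bit_flip_prob > 0:
            payloads = _apply_bit_flips(frames.payloads, recovered,
                                        impairment.bit_flip_prob,
                                        frames.spec.adc_bits, rng)
        else:
            payloads = frames.payloads  # shared: no corruption occurred
        streams.append(AntennaStream(antenna_id=a, payloads=payloads,
                                     recovered=recovered, spec=frames.spec))
    return streams
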