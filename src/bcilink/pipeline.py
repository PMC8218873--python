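"""End-to-end chains composing the signal, link, receiver and analysis stages.

`wireless_path` runs digitize -> frame -> transmit -> receive/upsample/upshift
in one call; `digitize_channelwise` builds the 12-bit code matrix one channel
at a time so that long multi-channel runs never materialize the native-rate
voltage matrix; `recover_unit_catalog` applies the standard spike-band
filter / threshold / sort stack used in the benchtop fidelity comparison.
"""

from __future__ import annotations

import numpy as np

from . import fidelity
from .link import CodeStream12, ImpairmentConfig, LinkSpec, adc_digitize, frame_stream, transmit
from .receiver import BridgeOutput, bridge
from .signals import BroadbandRecording, SignalConfig, SpikeTruth, synthesize_channel

__all__ = [
    "wireless_path",
    "transmit_and_bridge",
    "digitize_channelwise",
    "recover_unit_catalog",
]


def transmit_and_bridge(codes: CodeStream12,
                        impairment: ImpairmentConfig | None = None) -> BridgeOutput:
    frames = frame_stream(codes)
    return bridge(transmit(frames, impairment))


def wireless_path(recording: BroadbandRecording,
                  impairment: ImpairmentConfig | None = None,
                  spec: LinkSpec | None = None) -> BridgeOutput:
    """Full wireless chain from an analog-proxy recording to the 30 kS/s stream."""
    spec = spec or LinkSpec(n_channels=recording.n_channels)
    return transmit_and_bridge(adc_digitize(recording, spec), impairment)


def digitize_channelwise(config: SignalConfig, truth: list[SpikeTruth],
                         spec: LinkSpec | None = None) -> CodeStream12:
    """Synthesize and digitize one channel at a time (memory-bounded)."""
    spec = spec or LinkSpec(n_channels=config.n_channels)
    n20 = int(round(config.duration_s * spec.adc_rate))
    codes = np.empty((config.n_channels, n20), dtype=np.uint16)
    for ch in range(config.n_channels):
        x = synthesize_channel(config, truth, ch)
        rec = BroadbandRecording(data=x[None, :], rate=config.native_rate,
                                 channel_ids=[ch])
        codes[ch] = adc_digitize(rec, spec).codes[0, :n20]
    return CodeStream12(codes=codes, spec=spec)


def recover_unit_catalog(stream_uv: np.ndarray, fs: float,
                         channels: np.ndarray | None = None,
                         min_events: int = 10,
                         scale_uv: float = 1.0) -> fidelity.UnitCatalog:
    """Spike-band filter, threshold detection and sorting, channel by channel.

    ``scale_uv`` converts integer sample streams to microvolts one channel at
    a time, so a long 16-bit recording is never copied to float as a whole.
    """
    x = np.atleast_2d(np.asarray(stream_uv))
    duration = x.shape[1] / fs
    units = []
    idx = range(x.shape[0]) if channels is None else channels
    uid = 0
    for ch in idx:
        row = np.asarray(x[ch:ch + 1], dtype=np.float64) * scale_uv
        f = fidelity.bandpass(row, fidelity.SPIKE_BAND, fs)
        ev = fidelity.detect_threshold_crossings(f, fs)
        cat = fidelity.sort_units(f, ev, fs, duration_s=duration,
                                  min_events=min_events)
        for u in cat.units:
            u.channel = ch
            u.unit_id = uid
            uid += 1
            units.append(u)
    return fidelity.UnitCatalog(units=units, fs=fs, duration_s=duration)
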