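#!/usr/bin/env python
"""Run the benchtop recording through the wireless chain, with impairments.

Digitizes at 20 kS/s / 12 bit, frames (24-bit sync + 96 x 12-bit codes),
transmits over two antennas with 1% Bernoulli frame loss and rare bit
flips, reconstructs the 30 kS/s / 16-bit stream with previous-frame
concealment, and stores the stream plus the receiver log.
"""

from pathlib import Path

import numpy as np

from bcilink import formats
from bcilink.link import ImpairmentConfig, LinkSpec, adc_digitize, frame_stream, transmit
from bcilink.receiver import bridge

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    recording = formats.read_broadband(OUT / "benchtop.bbnd")
    spec = LinkSpec(n_channels=recording.n_channels)
    codes = adc_digitize(recording, spec)
    impairment = ImpairmentConfig(drop_prob=0.01, bit_flip_prob=1e-6,
                                  n_antennas=2, seed=SEED)
    out = bridge(transmit(frame_stream(codes, spec), impairment))
    np.save(OUT / "wireless_stream.npy", out.stream)
    formats.write_receiver_log(OUT / "receiver_log.json", out.receiver_log)
    log = out.receiver_log
    print(f"{log.n_frames} frames transmitted; {log.n_concealed} concealed "
          f"({100 * log.n_concealed / log.n_frames:.3f}% — both antennas lost), "
          f"output {out.stream.shape[1]} samples at {out.rate:.0f} S/s")


if __name__ == "__main__":
    main()
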