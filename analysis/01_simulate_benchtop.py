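#!/usr/bin/env python
"""Generate the benchtop-style synthetic recording used by later stages.

Writes a seeded 8-channel, 30 s broadband recording (three spiking units at
3.6 Hz per channel, 10.6 / 19.6 Hz oscillations, pink + white noise) plus
its ground-truth spike trains under results/.
"""

from pathlib import Path

from bcilink import formats
from bcilink.signals import generate_spike_truth, nss_preset, synthesize_broadband

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    config = nss_preset(n_channels=8, duration_s=30.0, seed=SEED)
    truth = generate_spike_truth(config)
    recording = synthesize_broadband(config, truth)
    formats.write_broadband(OUT / "benchtop.bbnd", recording, seed=SEED)
    formats.write_truth(OUT / "benchtop_truth.json", truth)
    n_spikes = sum(t.spike_times.size for t in truth)
    print(f"wrote {OUT / 'benchtop.bbnd'}: {recording.n_channels} channels x "
          f"{recording.duration_s:.0f} s at {recording.rate:.0f} S/s, "
          f"{n_spikes} ground-truth spikes "
          f"({n_spikes / recording.n_channels / recording.duration_s / 3:.2f} Hz "
          f"per unit, 3 units per channel)")


if __name__ == "__main__":
    main()
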