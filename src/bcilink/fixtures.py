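"""Seeded canonical fixtures with ground-truth manifests.

`make_fixtures` writes a small synthetic benchtop recording, a frame stream
carrying a known set of injected frame drops and MSB bit flips (positions
recorded in the manifest), and a two-block grid-task run — everything a
test harness needs to exercise the chain offline, reproducibly from one
seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import decoder as dec
from . import formats
from .link import LinkSpec, adc_digitize, frame_stream
from .signals import nss_preset, generate_spike_truth, synthesize_broadband

__all__ = ["make_fixtures"]

N_DROPS = 10
N_FLIPS = 5


def make_fixtures(seed: int, out_dir: str | Path,
                  n_channels: int = 8, duration_s: float = 10.0) -> dict:
    """Generate the fixture set; returns (and writes) the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([seed, 23])

    config = nss_preset(n_channels=n_channels, duration_s=duration_s, seed=seed)
    truth = generate_spike_truth(config)
    recording = synthesize_broadband(config, truth)
    formats.write_broadband(out / "nss_recording.bbnd", recording, seed=seed)
    formats.write_truth(out / "nss_truth.json", truth)

    spec = LinkSpec(n_channels=n_channels)
    codes = adc_digitize(recording, spec)
    frames = frame_stream(codes)

    n = frames.n_frames
    drop_positions = np.sort(rng.choice(n, size=N_DROPS, replace=False))
    flip_frames = np.sort(rng.choice(
        np.setdiff1d(np.arange(n), drop_positions), size=N_FLIPS, replace=False))
    flip_channels = rng.integers(0, n_channels, size=N_FLIPS)
    corrupted = frames.payloads.copy()
    for f, ch in zip(flip_frames, flip_channels):
        corrupted[f, ch] ^= 1 << (spec.adc_bits - 1)  # MSB flip
    from .link import FrameStream

    formats.write_frames(out / "frames_impaired.bwdf",
                         FrameStream(payloads=corrupted, spec=spec))

    user = dec.make_synthetic_user(n_channels=96, seed=seed)
    decoder = dec.calibrate_from_user(user, duration_s=60.0, seed=seed)
    blocks = []
    for b in range(2):
        res = dec.run_grid_task(decoder, user, seed=seed * 100 + b)
        blocks.append(dec.performance_metrics(res))

    manifest = {
        "seed": seed,
        "n_channels": n_channels,
        "duration_s": duration_s,
        "drop_frames": drop_positions.tolist(),
        "flip_frames": flip_frames.tolist(),
        "flip_channels": flip_channels.tolist(),
        "grid_blocks": blocks,
        "files": ["nss_recording.bbnd", "nss_truth.json", "frames_impaired.bwdf"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
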