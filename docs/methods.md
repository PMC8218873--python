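# Methods

This note documents the models, parameter choices and numerical
conventions behind `bcilink`, and what its synthetic benchmarks do and do
not establish about real recordings.

## Signal model

Each channel of the synthetic broadband voltage is the sum of four
independent components at a 60 kS/s "analog-proxy" rate:

```
v(t) = Σ_units Σ_spikes w(t − t_spike)  +  Σ_osc a_k sin(2π f_k t + φ_k)
       + pink(t) + white(t)                                   [µV]
```

- **Spike trains** are renewal processes: a hard refractory dead time
  (default 1.5 ms) plus an exponential tail whose rate is set so the mean
  interval equals `1/rate`. For rate `r` and refractory `d`, the count
  over `T` has mean `rT` and variance `T·(1/r − d)² · r³`, which the tests
  use as the oracle. The benchtop preset fires every unit at **3.6 Hz**.
- **Waveforms**: the benchtop source's actual shapes are unpublished; the
  preset uses three analytically defined templates (narrow biphasic
  ~60 µV, wide biphasic ~120 µV, triphasic ~240 µV peak) constructed so
  every pairwise peak-aligned correlation is below 0.9 — distinct enough
  for an unsupervised sorter, similar enough to be a meaningful test.
- **Oscillations** default to pure tones at 10.6 and 19.6 Hz (the band
  centers prominent in day-long human recordings), shared across channels
  as a common field source; placeholder values, configurable.
- **Noise**: white noise (default 6.5 µV RMS, matching the wired spike-band
  residual scale) and 1/f-shaped noise over 1–1000 Hz (default 10 µV RMS),
  independent per channel.

Every component draws from its own seed stream keyed by
`(seed, component, channel)`, making recordings bit-reproducible and
exactly additive across component subsets. The 60 kS/s proxy rate lets
both the wired path (30 kS/s) and the wireless ADC (20 kS/s) be derived
from one common source for A/B comparisons.

Not modeled: electrode impedance, tissue biophysics, unit drift or any
nonstationarity. Passing A/B tests therefore demonstrates fidelity of the
*digital chain*, not robustness to the biological variability that
dominates discrepancies in real sessions.

## Wireless chain conventions

- **ADC**: offset binary, LSB 4 µV, 0 µV ↔ code 2048, saturation at
  0/4095. After the receiver's four-bit up-shift this yields the familiar
  0.25 µV 16-bit grid. The transmitter's hardware filter (1 Hz – 7.8 kHz)
  and the wired front end (0.3 Hz – 7.5 kHz) are modeled as 4th-order
  Butterworth bandpasses applied zero-phase; resampling is polyphase.
- **Framing**: 24-bit sync word `0xB4D5A3` (any value works — sync loss is
  an explicit event, never inferred from payload content) + 96 × 12-bit
  codes = 1176 bits per 50 µs frame. Manchester coding uses the IEEE
  convention (0 → 10, 1 → 01).
- **Impairments**: frame loss is Bernoulli or Gilbert–Elliott (provided
  because in-home blockage produces bursty loss); payload bit flips are
  i.i.d. per bit on recovered frames. Flips are applied to payload bits
  rather than line symbols — observed errors are payload-level, and
  symbol-level simulation adds nothing testable.
- **Receiver**: a frame is valid if any antenna recovered it (lowest
  antenna index wins; the real selection rule is undocumented). Frames
  lost on all antennas repeat the previous valid frame on all channels; a
  leading drop emits mid-scale. Sample-and-hold upsampling with both
  clocks starting at t = 0 emits `(s1, s1, s2)` per input pair, so output
  index `j` is a repeat iff `j mod 3 = 1`.

## Error mitigation

A sample is flagged when it steps **≥ 500 µV from its predecessor**
(inclusive boundary; 15 µV/µs at 33 µs/sample). A large step that
immediately returns to within 500 µV of the pre-glitch level is the
glitch's return edge, not a new error, and is not flagged; an exact
repeat of a flagged value (the upsample-repeat case) extends the flag.
Repair replaces each flagged sample with the most recent unflagged sample
on that channel, in index order; a flag at index 0 becomes mid-scale.
Repair is idempotent on the signals tested. Digital-noise epochs open when
≥ 3 flags (default) fall within 300 ms on one channel — the qualitative
description ("recurring over tens to hundreds of milliseconds") pinned to
concrete defaults.

Detection runs on the 30 kS/s stream; whether the deployed system repaired
before or after upsampling is unstated, and the choice only affects which
of two duplicate samples is rewritten.

## Integrity statistics

Severely Errored Seconds tile the stream in non-overlapping 1 s windows
anchored at t = 0 (the anchor phase is unspecified in the source
definition); a window counts when **lost frames ≥ 50 %** (inclusive), and
a partial trailing window is excluded. SES is defined at the 20 kS/s frame
level, where loss events live. Disruption timelines partition a recording
into 300 s segments; a segment is disrupted when it contains any SES or
overlaps any unrecorded gap (the qualitative "unrecorded data or noise"
criterion made concrete). Spectra use Welch periodograms (4 s Hann
windows, 50 % overlap → 0.25 Hz resolution); peaks are local maxima of
the log-PSD with ≥ 6 dB prominence. Total Welch power matches time-domain
variance within 1 % (verified per segment).

## Spike detection and sorting

Threshold crossings use −4.5 × the per-channel noise RMS with the noise
estimated robustly as `median(|x|)/0.6745`, so the spikes themselves do
not inflate the threshold, with a 1 ms lockout. Snippets span −0.5/+1.1 ms
around the trough (searched up to 0.9 ms past the crossing). Sorting is
deterministic correlation-linkage: a leader pass against running template
means at a 0.9 correlation threshold, agglomerative merging of templates
at the same threshold using peak-aligned correlation (robust to alignment
modes), then re-assignment of every snippet to the nearest template in
Euclidean distance (amplitude-aware, since correlation is scale-blind).
Clusters below max(10 events, 2 % of the channel's snippets) are dropped;
the fraction floor keeps rare threshold-level noise crossings from
surviving as spurious units on long recordings.

## Decoder and Grid Task

Features are 20 ms bins of threshold-crossing counts and decode-band
(250 Hz – 5 kHz, two-pass zero-phase) power, after common average
referencing over the 32 lowest-RMS channels (the subset rule is this
package's choice). The velocity Kalman filter has AR(1) state dynamics
fitted from calibration kinematics, an observation model fit by least
squares, diagonal observation noise from residuals, and a steady-state
gain from the discrete algebraic Riccati equation. The click classifier is
a shared-covariance LDA.

The closed loop runs at the feature level: a synthetic cosine-tuned
population (96 channels, baseline 10 Hz, modulation 10 Hz — modulation
depth 1, "high SNR") emits Poisson counts for an intent velocity aimed at
the target (speed 0.4 workspace units/s, ramping down within 0.12 units of
the target, 0.05 units/s isotropic intent noise). Packet loss enters as
binomial thinning of counts by the fraction of each bin's 400 frames that
were dropped — spikes falling in concealed frames are repeats of old data
and cannot be detected. The Grid Task is 6×6 point-and-dwell: 1.0 s dwell
in any cell selects it (the starting cell re-arms only after the cursor
leaves it), 10 s timeout, 120 s blocks. Percent correct is
`100·Sc/(Sc+Si)`; bitrate `log2(N−1)·max(Sc−Si,0)/t`; path efficiency is
straight-line distance over path length; angle error is the mean absolute
angle between decoded velocity and the cursor-to-target vector.

The synthetic user is a stand-in for a participant: it validates that the
calibrate → decode → select loop closes and how it degrades under packet
loss, not any human performance level.

## Problem sizes

Tests run on scaled-down versions of each analysis (typically 1–4 channels
and 10–300 s); the acceptance script uses the full 96-channel benchtop
preset over 120 s, processing channel by channel so the native-rate matrix
is never materialized. The recovered-rate estimate is duration-insensitive:
per-unit sampling error at 120 s is ~0.17 Hz and the median over ~288
units suppresses it well below the 0.1 Hz reporting precision.

## Known limitations

- The benchtop source's waveform shapes, oscillation frequencies and noise
  floor are not published; defaults are documented placeholders.
- The sorter distinguishes units by waveform shape and amplitude; two
  units with identical shape and amplitude on one channel would merge.
- The Gilbert–Elliott chain is simulated sequentially (Python loop), fine
  for ≤10⁶ frames but not optimized beyond that.
- Clock-domain bit errors associated with the real upsampling logic are
  reproduced phenomenologically (optional repeat-frame corruption), not
  mechanistically — their hardware cause is unknown.
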