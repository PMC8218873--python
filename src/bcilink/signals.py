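"""Synthetic broadband multielectrode signals with known ground truth.

Emulates two signal sources on which the wireless chain is assessed:

* a benchtop neural signal simulator that superimposes noise, low-frequency
  oscillations and action potentials from three spiking units with distinct
  waveform shapes, replicated identically across all 96 electrodes; and
* human-like intracortical activity (LFP oscillations, spiking units,
  1/f + white noise).

Everything is seeded and bit-reproducible.  Each additive component (pink
noise, white noise, each oscillation, spikes) draws from its own seed stream
derived from ``(config.seed, channel, component)``, so a config with a subset
of components enabled produces exactly the same realization of those
components as the full config — recordings are additive sample-for-sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "UnitSpec",
    "SpikeTruth",
    "SignalConfig",
    "BroadbandRecording",
    "nss_preset",
    "generate_spike_truth",
    "synthesize_channel",
    "synthesize_broadband",
    "biphasic_template",
    "triphasic_template",
]

# benchtop simulator firing rate, identical for every unit on every channel
NSS_RATE_HZ = 3.6

# component codes for per-component seed streams
_COMP_SPIKES = 0
_COMP_PINK = 1
_COMP_WHITE = 2
_COMP_LFP = 3  # + oscillation index


def _gauss(t: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sd) ** 2)


def biphasic_template(
    peak_uv: float,
    rate: float,
    trough_ms: float = 0.10,
    rebound_ms: float = 0.20,
    rebound_frac: float = 0.30,
    support_ms: float = 1.6,
) -> np.ndarray:
    """Negative-going biphasic action-potential template sampled at `rate`.

    `trough_ms` / `rebound_ms` are the widths (Gaussian sd) of the negative
    trough and the positive after-potential; `rebound_frac` its relative
    amplitude.  Peak-to-trough amplitude is dominated by `peak_uv`.
    """
    n = int(round(support_ms * 1e-3 * rate))
    t = (np.arange(n) - n // 3) / rate * 1e3  # ms, trough near 1/3 of support
    w = -peak_uv * _gauss(t, 0.0, trough_ms)
    w += rebound_frac * peak_uv * _gauss(t, 3.2 * trough_ms + rebound_ms, rebound_ms)
    return w


def triphasic_template(
    peak_uv: float, rate: float, support_ms: float = 1.6
) -> np.ndarray:
    """Triphasic template: initial positivity, deep trough, slow rebound."""
    n = int(round(support_ms * 1e-3 * rate))
    t = (np.arange(n) - n // 3) / rate * 1e3
    w = 0.80 * peak_uv * _gauss(t, -0.45, 0.20)
    w -= peak_uv * _gauss(t, 0.0, 0.12)
    w += 0.20 * peak_uv * _gauss(t, 0.55, 0.35)
    return w


@dataclass(frozen=True)
class UnitSpec:
    """One simulated spiking unit assigned to one channel."""

    unit_id: int
    channel: int
    rate_hz: float
    template: np.ndarray  # uV, sampled at the config's native rate
    refractory_ms: float = 1.5

    def __post_init__(self) -> None:
        if self.rate_hz < 0:
            raise ValueError("rate_hz must be >= 0")
        if self.refractory_ms <= 0:
            raise ValueError("refractory_ms must be > 0")
        if self.rate_hz > 0 and np.ptp(self.template) <= 0:
            raise ValueError("template peak-to-peak must be > 0")


@dataclass(frozen=True)
class SpikeTruth:
    """Ground-truth spike train for one unit."""

    unit_id: int
    channel: int
    spike_times: np.ndarray  # seconds, strictly increasing
    template: np.ndarray


@dataclass(frozen=True)
class SignalConfig:
    n_channels: int = 96
    duration_s: float = 10.0
    native_rate: float = 60_000.0  # analog-proxy rate before any ADC
    units: tuple[UnitSpec, ...] = ()
    lfp_components: tuple[tuple[float, float, float], ...] = ()  # (Hz, uV, bw Hz)
    pink_noise_rms: float = 0.0
    white_noise_rms: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s < 0:
            raise ValueError("duration_s must be >= 0")
        if self.native_rate < 60_000:
            raise ValueError("native_rate must be >= 60000 S/s")
        if self.pink_noise_rms < 0 or self.white_noise_rms < 0:
            raise ValueError("noise amplitudes must be >= 0")
        for f, a, bw in self.lfp_components:
            if a < 0 or bw < 0 or f <= 0:
                raise ValueError("lfp component amplitudes/bandwidths must be >= 0")
        for u in self.units:
            if not 0 <= u.channel < self.n_channels:
                raise ValueError(f"unit {u.unit_id} channel out of range")

    @property
    def n_native_samples(self) -> int:
        return int(round(self.duration_s * self.native_rate))


@dataclass
class BroadbandRecording:
    """Channels x samples voltage matrix in microvolts."""

    data: np.ndarray  # (n_channels, n_samples) float64 uV
    rate: float
    channel_ids: list[int] = field(default_factory=list)
    start_time: float = 0.0
    truth: list[SpikeTruth] | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))
        if not self.channel_ids:
            self.channel_ids = list(range(self.data.shape[0]))

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate


def nss_preset(
    n_channels: int = 96,
    duration_s: float = 60.0,
    native_rate: float = 60_000.0,
    seed: int = 0,
) -> SignalConfig:
    """Benchtop neural-signal-simulator preset.

    Three spiking units with mutually distinct waveform shapes (pairwise
    peak-aligned correlation < 0.9) on every channel, all firing at the
    identical benchtop rate of 3.6 Hz, plus low-frequency oscillations and
    pink + white noise.  The published description of the benchtop source
    does not give waveform shapes, oscillation frequencies or noise levels;
    the amplitudes here (60/120/240 uV peak) and the 10.6 / 19.6 Hz
    oscillations are this package's documented defaults.
    """
    templates = (
        biphasic_template(60.0, native_rate, trough_ms=0.07, rebound_ms=0.14),
        biphasic_template(120.0, native_rate, trough_ms=0.16, rebound_ms=0.34,
                          rebound_frac=0.45),
        triphasic_template(240.0, native_rate),
    )
    units = tuple(
        UnitSpec(unit_id=3 * ch + k, channel=ch, rate_hz=NSS_RATE_HZ,
                 template=templates[k], refractory_ms=1.5)
        for ch in range(n_channels)
        for k in range(3)
    )
    return SignalConfig(
        n_channels=n_channels,
        duration_s=duration_s,
        native_rate=native_rate,
        units=units,
        lfp_components=((10.6, 20.0, 0.0), (19.6, 12.0, 0.0)),
        pink_noise_rms=10.0,
        white_noise_rms=6.5,
        seed=seed,
    )


def template_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two waveforms after aligning their troughs."""
    ia, ib = int(np.argmin(a)), int(np.argmin(b))
    shift = ib - ia
    if shift > 0:
        a, b = a[: len(a) - shift] if shift else a, b[shift:]
    elif shift < 0:
        a, b = a[-shift:], b[: len(b) + shift]
    n = min(len(a), len(b))
    a, b = a[:n], b[:n]
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def generate_spike_truth(config: SignalConfig, seed: int | None = None) -> list[SpikeTruth]:
    """Draw spike trains for every unit from a renewal process.

    Inter-spike intervals are a hard refractory dead time plus an exponential
    tail whose rate is set so the mean interval equals ``1 / rate_hz``
    (a Poisson process with dead time).  Spikes are kept strictly inside the
    recording so the full template support fits before ``duration_s``.
    """
    if seed is None:
        seed = config.seed
    out: list[SpikeTruth] = []
    for k, u in enumerate(config.units):
        rng = np.random.default_rng([int(seed), _COMP_SPIKES, int(u.channel), k])
        t_max = config.duration_s - len(u.template) / config.native_rate
        times: list[float] = []
        if u.rate_hz > 0 and t_max > 0:
            refr = u.refractory_ms * 1e-3
            mean_isi = 1.0 / u.rate_hz
            if mean_isi <= refr:
                raise ValueError(
                    f"unit {u.unit_id}: rate {u.rate_hz} Hz incompatible with "
                    f"{u.refractory_ms} ms refractory period"
                )
            tail = mean_isi - refr
            t = rng.exponential(mean_isi)  # equilibrium-ish start
            while t < t_max:
                times.append(t)
                t += refr + rng.exponential(tail)
        out.append(
            SpikeTruth(
                unit_id=u.unit_id,
                channel=u.channel,
                spike_times=np.asarray(times, dtype=float),
                template=u.template,
            )
        )
    return out


def renewal_count_moments(rate_hz: float, refractory_ms: float, duration_s: float):
    """Asymptotic mean and variance of the renewal spike count.

    For a renewal process with interval mean ``mu`` and variance ``s2`` the
    count over ``T`` has mean ``T/mu`` and variance ``T * s2 / mu**3``.
    """
    mu = 1.0 / rate_hz
    s2 = (mu - refractory_ms * 1e-3) ** 2  # exponential tail variance
    return duration_s / mu, duration_s * s2 / mu**3


def _pink_noise(n: int, rms: float, rate: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-shaped noise over 1–1000 Hz, flat outside, scaled to target RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = np.ones_like(f)
    band = (f >= 1.0) & (f <= 1000.0)
    shape[band] = np.sqrt(1.0 / f[band])
    shape[f > 1000.0] = np.sqrt(1.0 / 1000.0)
    shape[f < 1.0] = 1.0
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def synthesize_channel(
    config: SignalConfig, truth: list[SpikeTruth], channel: int
) -> np.ndarray:
    """One channel of the broadband voltage (uV) at the native rate.

    Public so that long recordings can be generated and consumed channel by
    channel without materializing the full channels x samples matrix.
    """
    n = config.n_native_samples
    x = np.zeros(n)
    # spikes
    for tr in truth:
        if tr.channel != channel or tr.spike_times.size == 0:
            continue
        if tr.spike_times.max() >= config.duration_s:
            raise ValueError(
                f"unit {tr.unit_id}: spike at {tr.spike_times.max():.3f} s "
                f"beyond recording duration {config.duration_s} s"
            )
        idx = np.round(tr.spike_times * config.native_rate).astype(int)
        m = len(tr.template)
        for i in idx:
            stop = min(i + m, n)
            x[i:stop] += tr.template[: stop - i]
    # oscillations: common across channels (a shared field source)
    t = np.arange(n) / config.native_rate
    for j, (f0, amp, bw) in enumerate(config.lfp_components):
        if amp == 0:
            continue
        rng = np.random.default_rng([config.seed, _COMP_LFP + j])
        phase = rng.uniform(0, 2 * np.pi)
        if bw <= 0:
            x += amp * np.sin(2 * np.pi * f0 * t + phase)
        else:
            nb = rng.standard_normal(n)
            lo, hi = max(f0 - bw / 2, 0.1), f0 + bw / 2
            sos = sps.butter(2, [lo, hi], btype="bandpass",
                             fs=config.native_rate, output="sos")
            nb = sps.sosfiltfilt(sos, nb)
            x += nb * (amp / np.sqrt(2) / nb.std())
    # noise, per channel
    if config.pink_noise_rms > 0:
        rng = np.random.default_rng([config.seed, _COMP_PINK, channel])
        x += _pink_noise(n, config.pink_noise_rms, config.native_rate, rng)
    if config.white_noise_rms > 0:
        rng = np.random.default_rng([config.seed, _COMP_WHITE, channel])
        x += config.white_noise_rms * rng.standard_normal(n)
    return x


def synthesize_broadband(
    config: SignalConfig, truth: list[SpikeTruth] | None = None
) -> BroadbandRecording:
    """Full recording: spikes + oscillations + pink + white noise per channel."""
    if truth is None:
        truth = generate_spike_truth(config)
    data = np.empty((config.n_channels, config.n_native_samples))
    for ch in range(config.n_channels):
        data[ch] = synthesize_channel(config, truth, ch)
    return BroadbandRecording(
        data=data, rate=config.native_rate,
        channel_ids=list(range(config.n_channels)), truth=truth,
    )
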