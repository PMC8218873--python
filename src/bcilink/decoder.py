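"""Closed-loop cursor decoding and Grid-Task assessment.

A steady-state Kalman filter estimates 2-D cursor velocity from binned
neural features (threshold-crossing counts, optionally spike-band power); a
linear discriminant classifier estimates click state.  Closed-loop
performance is assessed with a point-and-dwell Grid Task (6x6 targets,
2-minute blocks) driven by a synthetic cosine-tuned population standing in
for the participant, and summarized by the standard metrics: percent
correct, achieved bitrate ``log2(N-1) * max(Sc - Si, 0) / t``, trial
duration, path efficiency and angle error.

Packet loss couples into the loop through binomial thinning of the
threshold-crossing counts: spikes falling in concealed (dropped) frames are
repeats of old data and are not detected, so a drop fraction ``f`` within a
bin removes each count independently with probability ``f``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from . import fidelity

__all__ = [
    "FeatureFrame",
    "extract_features",
    "KalmanDecoder",
    "calibrate_kalman",
    "decode_velocity",
    "train_click_classifier",
    "classify_click",
    "SyntheticUser",
    "make_synthetic_user",
    "calibrate_from_user",
    "GridTaskConfig",
    "GridTaskResult",
    "Trial",
    "run_grid_task",
    "performance_metrics",
    "bitrate_bps",
    "typing_rate_ccpm",
]

BIN_MS_DEFAULT = 20.0


@dataclass
class FeatureFrame:
    """Binned neural features: per channel per bin."""

    counts: np.ndarray  # (n_bins, n_channels) threshold crossings
    power: np.ndarray  # (n_bins, n_channels) mean squared decode-band voltage (uV^2)
    bin_s: float


def extract_features(stream_uv: np.ndarray, fs: float,
                     bin_ms: float = BIN_MS_DEFAULT,
                     car_subset: np.ndarray | None = None,
                     thresholds_uv: np.ndarray | None = None) -> FeatureFrame:
    """CAR -> two-pass decode-band filter -> binned crossings and band power.

    A trailing partial bin is dropped.  Thresholds default to -4.5 x the
    per-channel RMS of the filtered signal.
    """
    x = np.atleast_2d(np.asarray(stream_uv))
    if car_subset is not None:
        x = fidelity.common_average_reference(x, car_subset)
    f = fidelity.bandpass(x, fidelity.DECODE_BAND, fs)
    events = fidelity.detect_threshold_crossings(f, fs, thresholds_uv=thresholds_uv)
    bin_n = int(round(bin_ms * 1e-3 * fs))
    n_bins = f.shape[1] // bin_n
    counts = np.zeros((n_bins, f.shape[0]))
    for ch, ev in enumerate(events):
        ev = ev[ev < n_bins * bin_n]
        np.add.at(counts[:, ch], ev // bin_n, 1)
    power = (f[:, : n_bins * bin_n] ** 2).reshape(f.shape[0], n_bins, bin_n).mean(axis=2).T
    return FeatureFrame(counts=counts, power=power, bin_s=bin_ms * 1e-3)


@dataclass
class KalmanDecoder:
    """Steady-state velocity Kalman filter.

    State: 2-D velocity with AR(1) dynamics ``v_t = A v_{t-1} + w``;
    observation ``x_t = H v_t + c + q`` with diagonal noise covariance R
    estimated from calibration residuals.  The steady-state gain is
    precomputed from the discrete algebraic Riccati equation.
    """

    A: np.ndarray  # (2, 2)
    W: np.ndarray  # (2, 2)
    H: np.ndarray  # (d, 2)
    c: np.ndarray  # (d,)
    R: np.ndarray  # (d, d)
    K: np.ndarray  # (2, d) steady-state gain
    kept_channels: np.ndarray  # feature columns used by the fit
    state: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def reset(self) -> None:
        self.state = np.zeros(2)

    def step(self, features: np.ndarray) -> np.ndarray:
        x = np.asarray(features, dtype=float).ravel()[self.kept_channels]
        v_pred = self.A @ self.state
        self.state = v_pred + self.K @ (x - self.c - self.H @ v_pred)
        return self.state.copy()


def _steady_state_gain(A: np.ndarray, W: np.ndarray, H: np.ndarray,
                       R: np.ndarray) -> np.ndarray:
    P = sla.solve_discrete_are(A.T, H.T, W, R)
    S = H @ P @ H.T + R
    return np.linalg.solve(S, (P @ H.T).T).T  # K = P H^T S^{-1}, S symmetric


def calibrate_kalman(features: np.ndarray, intended_velocity: np.ndarray,
                     min_duration_s: float = 60.0,
                     bin_s: float = BIN_MS_DEFAULT * 1e-3) -> KalmanDecoder:
    """Fit the observation model by least squares and build the decoder.

    Zero-variance feature columns are excluded from the fit.  Raises if the
    design is rank deficient (naming the offending columns) or if less than
    ``min_duration_s`` of paired data is supplied.
    """
    X = np.asarray(features, dtype=float)
    V = np.asarray(intended_velocity, dtype=float)
    if X.shape[0] != V.shape[0]:
        raise ValueError("features and kinematics must have equal bin counts")
    if X.shape[0] * bin_s < min_duration_s:
        raise ValueError(
            f"calibration needs >= {min_duration_s} s of paired data, got "
            f"{X.shape[0] * bin_s:.1f} s"
        )
    var = X.var(axis=0)
    kept = np.flatnonzero(var > 0)
    if kept.size == 0:
        raise ValueError("all feature columns have zero variance")
    Xk = X[:, kept]
    design = np.column_stack([V, np.ones(V.shape[0])])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient kinematics: intended velocity is degenerate")
    coef, *_ = np.linalg.lstsq(design, Xk, rcond=None)
    H = coef[:2].T  # (d, 2)
    c = coef[2]
    resid = Xk - design @ coef
    R = np.diag(np.maximum(resid.var(axis=0), 1e-12))
    # AR(1) velocity dynamics pooled over both axes
    num = float(np.sum(V[1:] * V[:-1]))
    den = float(np.sum(V[:-1] ** 2))
    a = num / den if den > 0 else 0.0
    a = float(np.clip(a, 0.0, 0.999))
    A = a * np.eye(2)
    w = V[1:] - a * V[:-1]
    W = np.cov(w.T) if w.shape[0] > 1 else np.eye(2) * 1e-4
    W = np.atleast_2d(W) + 1e-12 * np.eye(2)
    K = _steady_state_gain(A, W, H, R)
    return KalmanDecoder(A=A, W=W, H=H, c=c, R=R, K=K, kept_channels=kept)


def decode_velocity(decoder: KalmanDecoder, features: np.ndarray) -> np.ndarray:
    """One Kalman predict/update step; returns the 2-D velocity estimate."""
    return decoder.step(features)


def train_click_classifier(features: np.ndarray, labels: np.ndarray
                           ) -> LinearDiscriminantAnalysis:
    """Linear discriminant with shared covariance, threshold at equal posterior."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("click training needs both click and no-click examples")
    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=None)
    lda.fit(np.asarray(features, dtype=float), labels)
    return lda


def classify_click(lda: LinearDiscriminantAnalysis, features: np.ndarray) -> np.ndarray:
    return lda.predict(np.atleast_2d(np.asarray(features, dtype=float)))


@dataclass(frozen=True)
class SyntheticUser:
    """Cosine-tuned population standing in for the participant.

    Channel i fires at ``baseline + modulation * (pd_i . v) / v_norm``
    (rectified) and emits Poisson counts per bin.  The feedback policy aims
    at the target with speed ramping down near it, plus isotropic Gaussian
    intent noise.
    """

    preferred_dirs: np.ndarray  # (d, 2) unit vectors
    baseline_hz: np.ndarray  # (d,)
    modulation_hz: np.ndarray  # (d,)
    v_norm: float = 0.4  # workspace units/s mapped to full modulation depth
    intent_noise_sd: float = 0.05  # units/s on each velocity component
    ramp: float = 0.12  # distance (units) over which intent speed ramps down

    @property
    def n_channels(self) -> int:
        return self.preferred_dirs.shape[0]

    def intent(self, pos: np.ndarray, target: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
        d = target - pos
        dist = float(np.hypot(*d))
        if dist < 1e-12:
            v = np.zeros(2)
        else:
            v = d / dist * self.v_norm * min(1.0, dist / self.ramp)
        return v + rng.normal(0.0, self.intent_noise_sd, size=2)

    def emit_counts(self, v: np.ndarray, bin_s: float,
                    rng: np.random.Generator) -> np.ndarray:
        lam = self.baseline_hz + self.modulation_hz * (self.preferred_dirs @ v) / self.v_norm
        return rng.poisson(np.maximum(lam, 0.0) * bin_s).astype(float)


def make_synthetic_user(n_channels: int = 96, baseline_hz: float = 10.0,
                        modulation_hz: float = 10.0, seed: int = 0,
                        **kwargs) -> SyntheticUser:
    rng = np.random.default_rng([seed, 11])
    ang = rng.uniform(0, 2 * np.pi, n_channels)
    return SyntheticUser(
        preferred_dirs=np.column_stack([np.cos(ang), np.sin(ang)]),
        baseline_hz=np.full(n_channels, float(baseline_hz)),
        modulation_hz=np.full(n_channels, float(modulation_hz)),
        **kwargs,
    )


def calibrate_from_user(user: SyntheticUser, duration_s: float = 60.0,
                        bin_s: float = BIN_MS_DEFAULT * 1e-3,
                        seed: int = 0) -> KalmanDecoder:
    """Open-loop calibration: smooth random intended velocity + emitted counts."""
    rng = np.random.default_rng([seed, 13])
    n = int(round(duration_s / bin_s))
    # Ornstein-Uhlenbeck intended velocity, stationary sd ~ v_norm / sqrt(2)
    theta, sd = 0.98, user.v_norm / np.sqrt(2)
    V = np.zeros((n, 2))
    drive = rng.normal(0, sd * np.sqrt(1 - theta**2), size=(n, 2))
    for i in range(1, n):
        V[i] = theta * V[i - 1] + drive[i]
    X = np.stack([user.emit_counts(v, bin_s, rng) for v in V])
    return calibrate_kalman(X, V, min_duration_s=min(duration_s, 60.0), bin_s=bin_s)


@dataclass(frozen=True)
class GridTaskConfig:
    grid_size: int = 6  # 6x6 = 36 targets
    block_s: float = 120.0
    dwell_s: float = 1.0
    timeout_s: float = 10.0
    cursor_gain: float = 1.0
    bin_s: float = BIN_MS_DEFAULT * 1e-3
    drop_rate: float = 0.0  # wireless frame-drop probability
    frames_per_bin: int = 400  # 20 kS/s frames in one 20 ms bin

    def __post_init__(self) -> None:
        if self.grid_size**2 < 2:
            raise ValueError("grid must contain at least 2 targets")
        if self.dwell_s >= self.timeout_s:
            raise ValueError("dwell time must be shorter than the timeout")

    @property
    def n_targets(self) -> int:
        return self.grid_size**2


@dataclass
class Trial:
    target: int
    outcome: str  # "correct" | "incorrect" | "timeout"
    duration_s: float
    path: np.ndarray  # (n_steps, 2) cursor positions
    velocities: np.ndarray  # (n_steps, 2) decoded velocities
    start: np.ndarray
    target_center: np.ndarray


@dataclass
class GridTaskResult:
    trials: list[Trial]
    config: GridTaskConfig
    elapsed_s: float
    seed: int

    @property
    def n_correct(self) -> int:
        return sum(t.outcome == "correct" for t in self.trials)

    @property
    def n_incorrect(self) -> int:
        return sum(t.outcome == "incorrect" for t in self.trials)

    @property
    def n_timeout(self) -> int:
        return sum(t.outcome == "timeout" for t in self.trials)


def _cell_of(pos: np.ndarray, g: int) -> int:
    ij = np.clip((pos * g).astype(int), 0, g - 1)
    return int(ij[1] * g + ij[0])


def _cell_center(cell: int, g: int) -> np.ndarray:
    return np.array([(cell % g + 0.5) / g, (cell // g + 0.5) / g])


def run_grid_task(decoder: KalmanDecoder, user: SyntheticUser,
                  config: GridTaskConfig | None = None, seed: int = 0
                  ) -> GridTaskResult:
    """Closed-loop point-and-dwell Grid Task for one block.

    Each bin: the user emits features aimed at the current target, the
    decoder updates the cursor, and dwelling ``dwell_s`` inside any cell
    selects it (correct if it is the target).  A trial times out after
    ``timeout_s``; the block ends when ``block_s`` elapses (a trial in
    progress at that point is discarded).
    """
    config = config or GridTaskConfig()
    rng = np.random.default_rng([seed, 17])
    g = config.grid_size
    decoder.reset()
    pos = np.array([0.5, 0.5])
    t_total = 0.0
    trials: list[Trial] = []
    while t_total < config.block_s:
        # new target, never the cell the cursor currently occupies
        while True:
            target = int(rng.integers(config.n_targets))
            if target != _cell_of(pos, g):
                break
        t_center = _cell_center(target, g)
        start = pos.copy()
        path = [pos.copy()]
        vels = []
        dwell_t = 0.0
        dwell_cell = _cell_of(pos, g)
        armed = False  # the starting cell is selectable only after re-entry
        t_trial = 0.0
        outcome = None
        while outcome is None:
            if t_total >= config.block_s:
                break  # block expired mid-trial
            v_int = user.intent(pos, t_center, rng)
            counts = user.emit_counts(v_int, config.bin_s, rng)
            if config.drop_rate > 0:
                lost = rng.binomial(config.frames_per_bin, config.drop_rate)
                f = lost / config.frames_per_bin
                if f > 0:
                    counts = rng.binomial(counts.astype(int), 1.0 - f).astype(float)
            v = decoder.step(counts)
            pos = np.clip(pos + config.cursor_gain * v * config.bin_s, 0.0, 1.0)
            path.append(pos.copy())
            vels.append(v.copy())
            t_trial += config.bin_s
            t_total += config.bin_s
            cell = _cell_of(pos, g)
            if cell == dwell_cell:
                dwell_t += config.bin_s
            else:
                dwell_cell = cell
                dwell_t = config.bin_s
                armed = True
            if armed and dwell_t >= config.dwell_s:
                outcome = "correct" if cell == target else "incorrect"
            elif t_trial >= config.timeout_s:
                outcome = "timeout"
        if outcome is None:
            break  # discard incomplete trial
        trials.append(Trial(
            target=target, outcome=outcome, duration_s=t_trial,
            path=np.asarray(path), velocities=np.asarray(vels),
            start=start, target_center=t_center,
        ))
    return GridTaskResult(trials=trials, config=config, elapsed_s=t_total, seed=seed)


def bitrate_bps(n_targets: int, n_correct: int, n_incorrect: int,
                elapsed_s: float) -> float:
    """Achieved bitrate: log2(N-1) * max(Sc - Si, 0) / t."""
    if elapsed_s <= 0:
        raise ValueError("elapsed time must be positive")
    return np.log2(n_targets - 1) * max(n_correct - n_incorrect, 0) / elapsed_s


def typing_rate_ccpm(correct_characters: int, elapsed_minutes: float) -> float:
    """Free-typing rate in correct characters per minute.

    Deleted characters and backspaces count toward elapsed time but not
    toward the correct-character total.
    """
    if elapsed_minutes <= 0:
        raise ValueError("elapsed time must be positive")
    return correct_characters / elapsed_minutes


def performance_metrics(result: GridTaskResult,
                        config: GridTaskConfig | None = None) -> dict:
    """Percent correct, bitrate, trial duration, path efficiency, angle error."""
    config = config or result.config
    sc, si = result.n_correct, result.n_incorrect
    selections = sc + si
    durations = [t.duration_s for t in result.trials]
    path_eff, angle_err = [], []
    for t in result.trials:
        steps = np.diff(t.path, axis=0)
        path_len = float(np.hypot(steps[:, 0], steps[:, 1]).sum())
        straight = float(np.hypot(*(t.target_center - t.start)))
        if path_len > 0:
            path_eff.append(min(straight / path_len, 1.0))
        errs = []
        for p, v in zip(t.path[:-1], t.velocities):
            to_t = t.target_center - p
            nv, nt = np.hypot(*v), np.hypot(*to_t)
            if nv > 1e-12 and nt > 1e-12:
                cosang = np.clip(np.dot(v, to_t) / (nv * nt), -1.0, 1.0)
                errs.append(np.degrees(np.arccos(cosang)))
        if errs:
            angle_err.append(float(np.mean(errs)))
    return {
        "n_trials": len(result.trials),
        "n_correct": sc,
        "n_incorrect": si,
        "n_timeout": result.n_timeout,
        "percent_correct": 100.0 * sc / selections if selections else float("nan"),
        "bitrate_bps": bitrate_bps(config.n_targets, sc, si, result.elapsed_s),
        "mean_trial_duration_s": float(np.mean(durations)) if durations else float("nan"),
        "mean_path_efficiency": float(np.mean(path_eff)) if path_eff else float("nan"),
        "mean_angle_error_deg": float(np.mean(angle_err)) if angle_err else float("nan"),
        "elapsed_s": result.elapsed_s,
    }
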