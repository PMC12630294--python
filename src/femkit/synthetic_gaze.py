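"""Synthetic fixational gaze with known ground truth.

Generates 30-s fixation trials containing the ingredients the analysis
assumes: slow ocular drift (directed von-Mises random-walk or Brownian
diffusion), microsaccades from a dead-time-thinned Poisson process with
lognormal amplitudes and a uni- or bimodal von Mises direction mixture,
optional square-wave-jerk (SWJ) pairing, recentering of gaze by non-SWJ
saccades, additive sensor noise calibrated to a target RMS-S2S, and
occasional data-loss episodes.  Every draw flows through one seeded
generator, so identical config + seed give byte-identical output.

Defaults target the empirical regime of a high-precision retinal tracker
study: drift speed 0.76 deg/s, saccade rate ~1.8 Hz with ~0.25 deg median
displacement, sensor noise 0.156 arcmin RMS-S2S, and ~0.65% data loss.

Saccade kinematics use a raised-cosine position profile whose duration
follows a linear main-sequence rule (21 ms + 2.2 ms/deg); the analysis
measures displacement, not waveform shape, so any smooth monotone profile
of correct net displacement serves.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .gaze_io import TARGET_LABELS, GazeRecording, TrialManifest, TrialSpec

__all__ = [
    "SimulationConfig",
    "TrueSaccade",
    "GroundTruth",
    "simulate_drift",
    "sample_saccade_times",
    "saccade_waveform",
    "add_noise",
    "simulate_session",
    "match_saccades",
]

ARCMIN = 1.0 / 60.0  # deg


@dataclass
class SimulationConfig:
    """Generator parameters; defaults emulate the study conditions.

    Units: seconds, Hz, degrees of visual angle, arcmin where noted.
    ``amplitude_median``/``amplitude_log_sd`` parameterise a lognormal
    saccade amplitude; ``amplitude_min`` truncates it from below.
    ``direction_modes``/``direction_weights`` give one or two (opposed)
    von Mises saccade-direction modes.  ``recentering_gain`` is the fraction
    of the current offset from the trial center corrected by each non-SWJ
    saccade, which keeps 30-s traces near the target.
    """

    duration: float = 30.0  # s per trial
    rate: float = 620.0  # Hz
    n_trials: int = 1
    drift_mode: str = "directed"  # or "diffusion"
    drift_speed: float = 0.76  # deg/s target mean
    drift_direction_bias: float = 0.0  # deg
    drift_concentration: float = 50.0  # von Mises kappa of heading steps
    drift_bias_pull: float = 0.0  # optional heading reversion toward the bias
    saccade_rate: float = 1.8  # Hz
    refractory: float = 0.15  # s dead time
    amplitude_median: float = 0.25  # deg
    amplitude_log_sd: float = 0.35
    amplitude_min: float = 0.0  # deg, lower truncation
    direction_modes: tuple[float, ...] = (0.0, 180.0)  # deg
    direction_weights: tuple[float, ...] = (0.5, 0.5)
    direction_kappa: float = 8.0
    swj_fraction: float = 0.3
    swj_return_latency: float = 0.2  # s
    recentering_gain: float = 0.8
    noise_rms_s2s: float = 0.156  # arcmin
    loss_rate: float = 0.065  # Hz
    loss_duration: float = 0.1  # s
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.rate <= 0 or self.n_trials < 1:
            raise ConfigError("duration, rate and n_trials must be positive")
        if self.drift_mode not in ("directed", "diffusion"):
            raise ConfigError(f"unknown drift_mode {self.drift_mode!r}")
        if self.drift_speed < 0 or self.saccade_rate < 0 or self.refractory < 0:
            raise ConfigError("rates and durations must be nonnegative")
        if not 0.0 <= self.swj_fraction <= 1.0:
            raise ConfigError("swj_fraction must lie in [0, 1]")
        if not 0.0 <= self.recentering_gain <= 1.0:
            raise ConfigError("recentering_gain must lie in [0, 1]")
        if self.saccade_rate * self.refractory >= 1.0:
            raise ConfigError("infeasible: saccade_rate × refractory must be < 1")
        if len(self.direction_modes) != len(self.direction_weights):
            raise ConfigError("direction modes and weights must match in length")
        if self.noise_rms_s2s < 0 or self.loss_rate < 0 or self.loss_duration < 0:
            raise ConfigError("noise and loss parameters must be nonnegative")


@dataclass(frozen=True)
class TrueSaccade:
    """An injected saccade as executed (recording-global indices/times)."""

    onset_idx: int
    offset_idx: int
    onset_t: float
    offset_t: float
    amplitude: float  # deg, |net displacement|
    direction: float  # deg
    is_swj: bool
    swj_role: str = ""  # "primary" or "return" for SWJ members


@dataclass
class GroundTruth:
    """Everything the generator injected, sample-consistent with the output."""

    saccades: list[TrueSaccade]
    drift_path: np.ndarray  # (n, 2), noise- and saccade-free
    loss_intervals: list[tuple[float, float]]
    realized_saccade_rate: float

    def saccades_to_frame(self) -> pd.DataFrame:
        cols = ["onset_idx", "offset_idx", "onset_t", "offset_t",
                "amplitude_deg", "direction_deg", "is_swj", "swj_role"]
        rows = [
            {
                "onset_idx": s.onset_idx,
                "offset_idx": s.offset_idx,
                "onset_t": s.onset_t,
                "offset_t": s.offset_t,
                "amplitude_deg": s.amplitude,
                "direction_deg": s.direction,
                "is_swj": s.is_swj,
                "swj_role": s.swj_role,
            }
            for s in self.saccades
        ]
        return pd.DataFrame(rows, columns=cols)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Drift


def simulate_drift(config: SimulationConfig, seed=None, n: int | None = None) -> np.ndarray:
    """Noise-free drift path (n, 2) starting at the origin.

    Directed mode takes constant-length steps ``drift_speed/rate`` with a
    heading performing a von Mises random walk (weakly pulled back toward
    the bias direction), so the realized mean step speed equals the target
    exactly.  Diffusion mode takes isotropic Gaussian steps whose expected
    length matches the target speed.
    """
    rng = _rng(seed if seed is not None else config.seed)
    if n is None:
        n = int(round(config.duration * config.rate))
    step = config.drift_speed / config.rate
    if config.drift_mode == "directed":
        bias = math.radians(config.drift_direction_bias)
        jitter = rng.vonmises(0.0, config.drift_concentration, n - 1)
        headings = np.empty(n - 1)
        h = bias
        pull = config.drift_bias_pull
        for i in range(n - 1):
            h = h + jitter[i] + pull * math.sin(bias - h)
            headings[i] = h
        steps = step * np.column_stack((np.cos(headings), np.sin(headings)))
    else:
        # E|step| = s·sqrt(π/2) for per-axis SD s
        s = step / math.sqrt(math.pi / 2.0)
        steps = rng.normal(0.0, s, size=(n - 1, 2))
    path = np.vstack(([0.0, 0.0], np.cumsum(steps, axis=0)))
    return path


# ---------------------------------------------------------------------------
# Saccade timing and kinematics


def sample_saccade_times(
    config: SimulationConfig, seed=None, duration: float | None = None
) -> np.ndarray:
    """Saccade onset times: a Poisson process thinned by a dead time.

    Arrivals closer than ``refractory`` to the last kept arrival are
    discarded, so the realized rate is ≈ rate/(1 + rate·refractory).
    """
    rng = _rng(seed if seed is not None else config.seed)
    if duration is None:
        duration = config.duration
    if config.saccade_rate == 0:
        return np.array([])
    n = rng.poisson(config.saccade_rate * duration)
    times = np.sort(rng.uniform(0.0, duration, n))
    kept = []
    last = -math.inf
    for t in times:
        if t - last >= config.refractory:
            kept.append(t)
            last = t
    return np.array(kept)


def saccade_waveform(amplitude: float, direction: float, sr: float) -> np.ndarray:
    """Cumulative position offsets of a raised-cosine saccade.

    Duration follows the linear main-sequence rule
    ``max(6 ms, 21 ms + 2.2 ms/deg × amplitude)``.  Returns an (n, 2) array
    of offsets for the n samples after onset; the last row equals the net
    displacement (``amplitude`` in ``direction``) exactly.
    """
    if amplitude <= 0:
        raise ConfigError("amplitude must be positive")
    duration = max(0.006, 0.021 + 0.0022 * amplitude)
    n = max(2, int(round(duration * sr)))
    frac = 0.5 * (1.0 - np.cos(np.pi * np.arange(1, n + 1) / n))
    theta = math.radians(direction)
    return amplitude * np.column_stack((frac * math.cos(theta), frac * math.sin(theta)))


# ---------------------------------------------------------------------------
# Noise


def add_noise(
    recording: GazeRecording, noise_rms_s2s: float, seed=None
) -> GazeRecording:
    """Add i.i.d. Gaussian sensor noise calibrated to a target RMS-S2S.

    Per-axis SD is ``noise_rms_s2s / 2`` (arcmin → deg): for white noise
    E[Δx² + Δy²] = 4σ², so the measured RMS-S2S of a static trace matches
    the target.  A target of 0 returns the recording unchanged.
    """
    if noise_rms_s2s < 0:
        raise ConfigError("noise target must be nonnegative")
    if noise_rms_s2s == 0:
        return recording
    rng = _rng(seed)
    sd = noise_rms_s2s / 2.0 * ARCMIN
    noise = rng.normal(0.0, sd, size=(len(recording), 2))
    return GazeRecording(
        t=recording.t,
        x=recording.x + noise[:, 0],
        y=recording.y + noise[:, 1],
        valid=recording.valid,
        nominal_rate=recording.nominal_rate,
    )


# ---------------------------------------------------------------------------
# Session assembly


def _sample_amplitude(config: SimulationConfig, rng) -> float:
    a = config.amplitude_median * math.exp(config.amplitude_log_sd * rng.standard_normal())
    return max(a, config.amplitude_min)


def _sample_direction(config: SimulationConfig, rng) -> float:
    w = np.asarray(config.direction_weights, dtype=float)
    mode = rng.choice(len(w), p=w / w.sum())
    ang = rng.vonmises(math.radians(config.direction_modes[mode]), config.direction_kappa)
    return math.degrees(ang) % 360.0


def simulate_session(
    config: SimulationConfig, seed=None
) -> tuple[GazeRecording, GroundTruth, TrialManifest]:
    """Compose drift, saccades, SWJs, noise and loss into a full session.

    Each trial starts at the target center; non-SWJ saccades correct
    ``recentering_gain`` of the current offset on top of their sampled
    displacement vector, SWJ returns exactly undo their primary.  The
    emitted manifest holds ``n_trials`` contiguous pseudo-trials cycling
    through the five target labels; the ground truth records every executed
    saccade, the noise-free drift path, and all loss intervals.
    """
    rng = _rng(seed if seed is not None else config.seed)
    n = int(round(config.duration * config.rate))
    dt = 1.0 / config.rate
    guard = max(1, int(round(0.03 * config.rate)))  # min samples between injections

    all_t, all_x, all_y, all_valid = [], [], [], []
    drift_paths = []
    true_saccades: list[TrueSaccade] = []
    loss_intervals: list[tuple[float, float]] = []
    trials = []

    for k in range(config.n_trials):
        t0 = k * config.duration
        t_local = np.arange(n) * dt
        drift = simulate_drift(config, rng, n=n)

        # agenda of (time, kind, payload); primaries first, SWJ returns inserted
        agenda: list[tuple[float, str, tuple | None]] = [
            (tau, "primary", None) for tau in sample_saccade_times(config, rng)
        ]
        sac_contrib = np.zeros((n, 2))
        cum_vec = np.zeros(2)
        last_offset_idx = -guard - 1
        while agenda:
            tau, kind, payload = agenda.pop(0)
            i0 = int(np.searchsorted(t_local, tau))
            if i0 <= last_offset_idx + guard or i0 < 1 or i0 >= n - 1:
                continue
            if kind == "primary":
                amp = _sample_amplitude(config, rng)
                theta = _sample_direction(config, rng)
                is_swj = rng.uniform() < config.swj_fraction
                vec = amp * np.array(
                    [math.cos(math.radians(theta)), math.sin(math.radians(theta))]
                )
                if not is_swj and config.recentering_gain > 0:
                    pos_pre = drift[i0] + cum_vec
                    vec = vec - config.recentering_gain * pos_pre
            else:  # SWJ return: exactly undo the primary
                primary_vec, primary_idx = payload
                if primary_idx != len(true_saccades) - 1:
                    # another saccade intervened; the pending correction
                    # is superseded
                    continue
                vec = -np.asarray(primary_vec)
                is_swj = True
            mag = float(np.hypot(*vec))
            if mag < 1e-6:
                continue
            direction = math.degrees(math.atan2(vec[1], vec[0])) % 360.0
            wf = saccade_waveform(mag, direction, config.rate)
            nw = len(wf)
            if i0 + nw >= n - 1:
                continue
            sac_contrib[i0 + 1 : i0 + 1 + nw] += wf
            sac_contrib[i0 + 1 + nw :] += vec
            cum_vec = cum_vec + vec
            onset_idx = i0 + 1
            offset_idx = i0 + nw
            true_saccades.append(
                TrueSaccade(
                    onset_idx=k * n + onset_idx,
                    offset_idx=k * n + offset_idx,
                    onset_t=t0 + t_local[onset_idx],
                    offset_t=t0 + t_local[offset_idx],
                    amplitude=mag,
                    direction=direction,
                    is_swj=is_swj,
                    swj_role=("" if not is_swj
                              else ("primary" if kind == "primary" else "return")),
                )
            )
            last_offset_idx = offset_idx
            if kind == "primary" and is_swj:
                ret_t = t_local[offset_idx] + config.swj_return_latency
                bisect.insort(
                    agenda,
                    (ret_t, "return", (tuple(vec), len(true_saccades) - 1)),
                    key=lambda e: e[0],
                )

        xy = drift + sac_contrib
        x, y = xy[:, 0].copy(), xy[:, 1].copy()
        valid = np.ones(n, dtype=bool)

        if config.loss_rate > 0 and config.loss_duration > 0:
            n_loss = rng.poisson(config.loss_rate * config.duration)
            starts = np.sort(rng.uniform(0.0, config.duration, n_loss))
            for s in starts:
                sel = (t_local >= s) & (t_local < s + config.loss_duration)
                if sel.any():
                    valid[sel] = False
                    loss_intervals.append(
                        (t0 + s, t0 + min(s + config.loss_duration, config.duration))
                    )

        all_t.append(t0 + t_local)
        all_x.append(x)
        all_y.append(y)
        all_valid.append(valid)
        drift_paths.append(drift)
        trials.append(
            TrialSpec(
                label=TARGET_LABELS[k % len(TARGET_LABELS)],
                polarity="white-on-black",
                t_on=t0,
                t_off=t0 + config.duration,
                center=(0.0, 0.0),
            )
        )

    t = np.concatenate(all_t)
    x = np.concatenate(all_x)
    y = np.concatenate(all_y)
    valid = np.concatenate(all_valid)
    x[~valid] = np.nan
    y[~valid] = np.nan
    recording = GazeRecording(t=t, x=x, y=y, valid=valid, nominal_rate=config.rate)
    if config.noise_rms_s2s > 0:
        recording = add_noise(recording, config.noise_rms_s2s, rng)
        recording.x[~valid] = np.nan
        recording.y[~valid] = np.nan

    total_duration = config.n_trials * config.duration
    truth = GroundTruth(
        saccades=true_saccades,
        drift_path=np.vstack(drift_paths),
        loss_intervals=loss_intervals,
        realized_saccade_rate=len(true_saccades) / total_duration,
    )
    manifest = TrialManifest(trials=trials)
    return recording, truth, manifest


# ---------------------------------------------------------------------------
# Recovery evaluation


def match_saccades(
    truth: Sequence[TrueSaccade],
    detected,
    tol: float = 0.010,
) -> tuple[list[tuple[TrueSaccade, object]], list[TrueSaccade], list]:
    """Match injected to detected saccades by onset time.

    Greedy nearest-onset matching within ``tol`` seconds; each detected
    event matches at most one truth.  Returns (matched pairs, missed
    truths, unmatched detections i.e. false alarms).
    """
    det = sorted(detected, key=lambda s: s.onset_t)
    det_used = [False] * len(det)
    det_times = [s.onset_t for s in det]
    pairs, missed = [], []
    for tr in sorted(truth, key=lambda s: s.onset_t):
        j = bisect.bisect_left(det_times, tr.onset_t)
        best, best_err = None, tol
        for jj in (j - 1, j, j + 1):
            if 0 <= jj < len(det) and not det_used[jj]:
                err = abs(det_times[jj] - tr.onset_t)
                if err <= best_err:
                    best, best_err = jj, err
        if best is None:
            missed.append(tr)
        else:
            det_used[best] = True
            pairs.append((tr, det[best]))
    false_alarms = [d for d, used in zip(det, det_used) if not used]
    return pairs, missed, false_alarms
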