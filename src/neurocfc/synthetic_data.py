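"""Synthetic EEG and behavior with planted, recoverable ground truth.

Every downstream stage of the pipeline (spectral power, phase-to-power CFC,
PPC connectivity, nodal efficiency, cluster statistics, behavioral tests) is
exercised on data generated here, where the quantity each stage estimates is
planted with a known value:

* a dominant theta rhythm at a per-subject frequency in 3-8 Hz,
* high-gamma amplitude modulated by the theta phase with strength m in [0,1]
  (peak-coupled, matching the stimulation waveform's coupling geometry),
* inter-channel theta phase locking controlled by a per-channel wrapped-
  normal phase jitter (the hub channel carries no jitter, so hub-involving
  pairs are the most phase-consistent and the hub attains the highest nodal
  efficiency),
* 1/f pink background noise,
* occasional artifact trials that violate either the +/-100 uV amplitude or
  the 50 uV/ms gradient rejection rule (one rule per planted trial, so each
  criterion is independently testable),
* lognormal pre/post reaction-time tables with a multiplicative treatment
  effect on the treated group's post session.

Everything is deterministic given the seed, and the exact planted values are
returned in a :class:`GroundTruth` record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EpochsArray
from .montage import DEFAULT_CHANNELS, standard_positions

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "pink_noise",
    "generate_pac_signal",
    "generate_epochs",
    "generate_behavior",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for one synthetic recording session.

    Defaults mirror the study design: 60 trials per session sampled at
    500 Hz on a 10-20 montage, epochs from -2.5 to +0.5 s around the
    test-stimulus onset (covering the 2-s retention period), theta at 5 Hz
    with its 16th harmonic (80 Hz) amplitude-coupled at strength ``m``.
    """

    n_trials: int = 60
    n_channels: int = 28
    fs: float = 500.0
    epoch_window: tuple[float, float] = (-2.5, 0.5)
    theta_freq: float = 5.0                 # Hz, in [3, 8]
    gamma_freq: float | None = None         # Hz; default 16 x theta
    m: float = 0.5                          # coupling strength in [0, 1]
    a_theta: float = 10.0                   # uV
    a_gamma: float = 4.0                    # uV
    alpha_freq: float = 10.0                # Hz, ongoing alpha rhythm
    a_alpha: float = 0.0                    # uV; 0 disables the alpha component
    noise_sd: float = 5.0                   # uV, pink background
    noise_exponent: float = 1.0             # 1/f^exponent
    phase_jitter_sd: float = 0.5            # rad, non-hub channels
    jitter_overrides: dict = field(default_factory=dict)  # channel -> sd (rad)
    hub_channel: str = "F3"
    pac_channels: tuple[str, ...] | None = None   # None = all channels
    artifact_rate: float = 0.0              # fraction of trials
    seed: int = 0

    def __post_init__(self) -> None:
        gamma = self.gamma_freq if self.gamma_freq is not None else 16.0 * self.theta_freq
        object.__setattr__(self, "gamma_freq", float(gamma))
        if not 3.0 <= self.theta_freq <= 8.0:
            raise ValueError(f"theta_freq={self.theta_freq} outside [3, 8] Hz")
        if not 0.0 <= self.m <= 1.0:
            raise ValueError("coupling strength m must lie in [0, 1]")
        if self.fs <= 2.0 * self.gamma_freq:
            raise ValueError(
                f"fs={self.fs} Hz violates Nyquist for gamma_freq={self.gamma_freq} Hz"
            )
        if self.epoch_window[0] > -2.0 or self.epoch_window[1] < 0.0:
            raise ValueError("epoch window must span the retention period [-2, 0] s")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must lie in [0, 1]")
        if not 2 <= self.n_channels <= len(DEFAULT_CHANNELS):
            raise ValueError(f"n_channels must lie in [2, {len(DEFAULT_CHANNELS)}]")

    @property
    def channels(self) -> list[str]:
        chans = DEFAULT_CHANNELS[: self.n_channels]
        if self.hub_channel not in chans:
            raise ValueError(f"hub_channel {self.hub_channel!r} not in montage {chans}")
        return chans


@dataclass
class GroundTruth:
    """Exact planted parameters, recorded as used by the generator."""

    theta_freq: float
    gamma_freq: float
    coupling_strength: float
    pac_channels: list[str]
    hub_channel: str
    jitter_sd: dict                     # channel -> wrapped-normal sd (rad)
    channel_lags: dict                  # channel -> fixed theta phase lag (rad)
    artifact_trials: dict               # trial index -> "amplitude" | "gradient"
    seed: int


def pink_noise(
    n: int, rng: np.random.Generator, exponent: float = 1.0, shape: tuple = ()
) -> np.ndarray:
    """1/f^exponent noise, unit standard deviation, via spectral shaping."""
    white = rng.standard_normal(shape + (n,))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_pac_signal(
    theta_freq: float,
    gamma_freq: float,
    m: float,
    fs: float,
    duration: float,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    a_theta: float = 1.0,
    a_gamma: float = 1.0,
    theta_phase: float = 0.0,
    noise_exponent: float = 1.0,
) -> np.ndarray:
    """Single-channel phase-amplitude-coupled time series.

        x(t) = a_theta * sin(2*pi*f_theta*t + phi)
             + a_gamma * (1 + m * sin(2*pi*f_theta*t + phi)) / 2
                       * sin(2*pi*f_gamma*t)
             + noise_sd * pink noise

    so the gamma envelope peaks at theta peaks with modulation depth m.
    """
    if fs <= 2.0 * gamma_freq:
        raise ValueError(f"fs={fs} Hz violates Nyquist for gamma_freq={gamma_freq} Hz")
    if duration < 2.0:
        raise ValueError("duration must be at least 2 s")
    if not 0.0 <= m <= 1.0:
        raise ValueError("m must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    theta = np.sin(2 * np.pi * theta_freq * t + theta_phase)
    x = a_theta * theta
    x = x + a_gamma * (1.0 + m * theta) / 2.0 * np.sin(2 * np.pi * gamma_freq * t)
    if noise_sd > 0:
        x = x + noise_sd * pink_noise(n, rng, exponent=noise_exponent)
    return x


def _wrapped_normal(rng: np.random.Generator, sd: float, size) -> np.ndarray:
    return np.mod(rng.normal(0.0, sd, size) + np.pi, 2 * np.pi) - np.pi


def generate_epochs(config: SimulationConfig) -> tuple[EpochsArray, GroundTruth]:
    """Multichannel epochs with planted theta locking, PAC, noise, artifacts.

    Per trial, the hub channel carries a reference theta phase (uniform
    across trials); every other channel's theta phase is the reference plus
    a fixed per-channel lag plus wrapped-normal jitter of its configured sd.
    Gamma on each PAC channel is modulated by that channel's own theta
    phase with depth m.
    """
    channels = config.channels
    names, positions = standard_positions(channels)
    rng = np.random.default_rng(config.seed)
    n_samp = int(round((config.epoch_window[1] - config.epoch_window[0]) * config.fs))
    t = config.epoch_window[0] + np.arange(n_samp) / config.fs

    pac_set = set(channels if config.pac_channels is None else config.pac_channels)
    unknown = pac_set - set(channels)
    if unknown:
        raise ValueError(f"pac_channels not in montage: {sorted(unknown)}")

    jitter_sd = {}
    lags = {}
    for c in channels:
        if c == config.hub_channel:
            jitter_sd[c] = 0.0
        else:
            jitter_sd[c] = float(config.jitter_overrides.get(c, config.phase_jitter_sd))
        lags[c] = 0.0 if c == config.hub_channel else float(rng.uniform(-0.3, 0.3))

    data = np.zeros((config.n_trials, len(channels), n_samp))
    ref_phases = rng.uniform(0.0, 2 * np.pi, config.n_trials)
    for tr in range(config.n_trials):
        for ci, c in enumerate(channels):
            phi = ref_phases[tr] + lags[c]
            if jitter_sd[c] > 0:
                phi = phi + _wrapped_normal(rng, jitter_sd[c], ())
            theta = np.sin(2 * np.pi * config.theta_freq * t + phi)
            x = config.a_theta * theta
            if config.a_alpha > 0:
                x = x + config.a_alpha * np.sin(
                    2 * np.pi * config.alpha_freq * t + rng.uniform(0.0, 2 * np.pi)
                )
            if c in pac_set:
                gamma_phase = rng.uniform(0.0, 2 * np.pi)
                x = x + config.a_gamma * (1.0 + config.m * theta) / 2.0 * np.sin(
                    2 * np.pi * config.gamma_freq * t + gamma_phase
                )
            if config.noise_sd > 0:
                x = x + config.noise_sd * pink_noise(
                    n_samp, rng, exponent=config.noise_exponent
                )
            data[tr, ci] = x

    artifact_trials: dict[int, str] = {}
    n_art = int(round(config.artifact_rate * config.n_trials))
    if n_art:
        chosen = rng.choice(config.n_trials, size=n_art, replace=False)
        for k, tr in enumerate(sorted(chosen.tolist())):
            ch = int(rng.integers(len(channels)))
            if k % 2 == 0:
                # amplitude violation: smooth 130 uV bump, gentle gradient
                center = n_samp // 2
                sigma = 0.05 * config.fs
                bump = 130.0 * np.exp(-((np.arange(n_samp) - center) ** 2) / (2 * sigma**2))
                data[tr, ch] += bump
                artifact_trials[tr] = "amplitude"
            else:
                # gradient violation: +/-60 uV square alternation (120 uV jumps),
                # amplitude stays under the 100 uV rule
                i0 = n_samp // 3
                seg = np.arange(6)
                data[tr, ch, i0: i0 + 6] += 60.0 * (-1.0) ** seg
                artifact_trials[tr] = "gradient"

    epochs = EpochsArray(data, config.fs, names, positions, tmin=config.epoch_window[0])
    truth = GroundTruth(
        theta_freq=config.theta_freq,
        gamma_freq=float(config.gamma_freq),
        coupling_strength=config.m,
        pac_channels=sorted(pac_set),
        hub_channel=config.hub_channel,
        jitter_sd=jitter_sd,
        channel_lags=lags,
        artifact_trials=artifact_trials,
        seed=config.seed,
    )
    return epochs, truth


def generate_behavior(
    n_per_group: int,
    baseline_rt: float = 0.9,
    rt_effect: float = 0.85,
    seed: int = 0,
    n_trials: int = 60,
    sigma_log: float = 0.25,
    between_subject_sd: float = 0.1,
    accuracy: float = 0.9,
) -> pd.DataFrame:
    """Pre/post reaction-time tables for a treated and a sham group.

    Reaction times are lognormal around each subject's own baseline; the
    treated group's post-session RTs are scaled by ``rt_effect``
    (< 1 = speed-up).  Columns: subject, group, session, trial, rt_s,
    correct.
    """
    if baseline_rt <= 0:
        raise ValueError("baseline_rt must be positive")
    if not 0 < rt_effect <= 1.5:
        raise ValueError("rt_effect must be a positive multiplicative factor")
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for group in ("treated", "sham"):
        for _ in range(n_per_group):
            subject_base = baseline_rt * float(
                np.exp(rng.normal(0.0, between_subject_sd))
            )
            for session in ("pre", "post"):
                scale = rt_effect if (group == "treated" and session == "post") else 1.0
                rts = subject_base * scale * np.exp(
                    rng.normal(0.0, sigma_log, n_trials)
                )
                correct = rng.random(n_trials) < accuracy
                for tr in range(n_trials):
                    rows.append(
                        (f"S{sid:02d}", group, session, tr, float(rts[tr]), bool(correct[tr]))
                    )
            sid += 1
    return pd.DataFrame(
        rows, columns=["subject", "group", "session", "trial", "rt_s", "correct"]
    )
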