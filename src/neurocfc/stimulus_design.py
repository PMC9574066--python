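"""Individualized cross-frequency-coupled tACS waveform synthesis.

The stimulation current is a theta-phase / high-gamma-amplitude coupled
waveform delivered through a central electrode (F3) with four surrounding
return electrodes (Fp1, Fz, F7, C3), each carrying minus one quarter of the
stimulation current so the net injected current is exactly zero at every
sample:

    s(t) = (A_fA / 2) * (sin(2*pi*f_P*t) + 1) * sin(2*pi*f_A*t)
           + A_fP * sin(2*pi*f_P*t)
    return_k(t) = -s(t) / 4,   k = 1..4

The phase frequency f_P is the individual's dominant theta frequency
(3-8 Hz), and the amplitude frequency is locked to the 16th harmonic,
f_A = 16 * f_P, confined to the 50-100 Hz high-gamma range.  With the default
amplitude constants A_fA = 0.2 and A_fP = 0.8, the analytic envelope of s(t)
(treating the two phases as independent) spans [-0.8, +1.0], i.e. a 1.8
peak-to-peak range at unit current scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusParams",
    "WaveformSet",
    "ThetaPeak",
    "detect_theta_peak",
    "gamma_from_theta",
    "synthesize",
    "sham_waveform",
    "analytic_extrema",
]

GAMMA_HARMONIC = 16
GAMMA_RANGE_HZ = (50.0, 100.0)
THETA_BAND_HZ = (3.0, 8.0)


@dataclass(frozen=True)
class StimulusParams:
    """Design parameters for one subject's CFC-tACS waveform."""

    f_p: float                    # theta phase frequency, Hz
    f_a: float | None = None      # gamma amplitude frequency, Hz (default 16*f_p)
    a_fa: float = 0.2             # gamma amplitude constant
    a_fp: float = 0.8             # theta amplitude constant
    fs: float = 1000.0            # Hz
    duration: float = 1200.0      # s (20 min session)
    ramp: float = 10.0            # s, linear ramp-up/down
    current_scale: float = 1.0    # mA per unit amplitude

    def __post_init__(self) -> None:
        if not (THETA_BAND_HZ[0] <= self.f_p <= THETA_BAND_HZ[1]):
            raise ValueError(f"f_p={self.f_p} Hz outside theta band {THETA_BAND_HZ}")
        f_a = self.f_a if self.f_a is not None else gamma_from_theta(self.f_p)
        object.__setattr__(self, "f_a", float(f_a))
        if not (GAMMA_RANGE_HZ[0] <= self.f_a <= GAMMA_RANGE_HZ[1]):
            raise ValueError(f"f_a={self.f_a} Hz outside high-gamma range {GAMMA_RANGE_HZ}")
        if self.a_fa <= 0 or self.a_fp <= 0:
            raise ValueError("amplitude constants must be positive")
        if self.ramp < 0:
            raise ValueError("ramp must be non-negative")
        if self.fs <= 2 * self.f_a:
            raise ValueError(f"fs={self.fs} Hz violates Nyquist for f_a={self.f_a} Hz")
        if self.duration <= 2 * self.ramp:
            raise ValueError("duration must exceed twice the ramp time")


@dataclass
class WaveformSet:
    """Stimulation current (F3) and its four return currents, in mA."""

    stimulus: np.ndarray
    returns: np.ndarray          # (4, n_samples)
    fs: float
    return_labels: tuple[str, ...] = ("Fp1", "Fz", "F7", "C3")
    params: StimulusParams | None = None

    def __post_init__(self) -> None:
        if self.returns.shape != (4, self.stimulus.size):
            raise ValueError("need four return traces matching the stimulus length")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.stimulus.size) / self.fs

    def total_current(self) -> np.ndarray:
        """Stimulus + all returns; zero at every sample by construction."""
        return self.stimulus + self.returns.sum(axis=0)


@dataclass(frozen=True)
class ThetaPeak:
    frequency: float
    rule: str                    # "local_max" or "band_edge_global_max"
    power: float

    @property
    def used_fallback(self) -> bool:
        return self.rule == "band_edge_global_max"


def detect_theta_peak(
    freqs: np.ndarray,
    power: np.ndarray,
    band: tuple[float, float] = THETA_BAND_HZ,
) -> ThetaPeak:
    """Select the dominant theta frequency from a power spectrum.

    The highest interior local maximum within ``band`` wins.  When the
    band-restricted spectrum has no interior local maximum (e.g. a monotone
    1/f background), the band-restricted global maximum is used instead,
    which may sit on a band edge; the returned :class:`ThetaPeak` records
    which rule fired.  Ties break toward the lower frequency.
    """
    freqs = np.asarray(freqs, float)
    power = np.asarray(power, float)
    if freqs.shape != power.shape or freqs.ndim != 1:
        raise ValueError("freqs and power must be matching 1-D arrays")
    if freqs[0] > band[0] or freqs[-1] < band[1]:
        raise ValueError(f"spectrum {freqs[0]}-{freqs[-1]} Hz does not cover band {band}")
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("frequency axis must be strictly increasing")
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    fb, pb = freqs[in_band], power[in_band]
    if fb.size < 3:
        raise ValueError("fewer than 3 spectral bins inside the band")
    interior = np.flatnonzero((pb[1:-1] > pb[:-2]) & (pb[1:-1] >= pb[2:])) + 1
    if interior.size:
        best = interior[np.argmax(pb[interior])]
        return ThetaPeak(float(fb[best]), "local_max", float(pb[best]))
    best = int(np.argmax(pb))
    return ThetaPeak(float(fb[best]), "band_edge_global_max", float(pb[best]))


def gamma_from_theta(f_p: float) -> float:
    """Gamma amplitude frequency: 16 x individual theta, confined to 50-100 Hz."""
    if f_p <= 0:
        raise ValueError("theta frequency must be positive")
    f_a = GAMMA_HARMONIC * f_p
    if not (GAMMA_RANGE_HZ[0] <= f_a <= GAMMA_RANGE_HZ[1]):
        raise ValueError(
            f"16 x {f_p} Hz = {f_a} Hz falls outside the permitted "
            f"high-gamma range {GAMMA_RANGE_HZ}"
        )
    return float(f_a)


def _cfc_formula(t: np.ndarray, p: StimulusParams) -> np.ndarray:
    theta = np.sin(2 * np.pi * p.f_p * t)
    gamma = np.sin(2 * np.pi * p.f_a * t)
    return (p.a_fa / 2.0) * (theta + 1.0) * gamma + p.a_fp * theta


def _linear_ramp_envelope(n: int, fs: float, ramp: float) -> np.ndarray:
    env = np.ones(n)
    n_ramp = int(round(ramp * fs))
    if n_ramp > 0:
        up = np.arange(n_ramp) / n_ramp
        env[:n_ramp] = up
        env[n - n_ramp:] = up[::-1]
    return env


def synthesize(params: StimulusParams) -> WaveformSet:
    """Generate the ramped CFC stimulation waveform plus its four returns."""
    n = int(round(params.duration * params.fs))
    t = np.arange(n) / params.fs
    stim = _cfc_formula(t, params)
    stim *= _linear_ramp_envelope(n, params.fs, params.ramp)
    stim *= params.current_scale
    returns = np.tile(-stim / 4.0, (4, 1))
    return WaveformSet(stimulus=stim, returns=returns, fs=params.fs, params=params)


def sham_waveform(params: StimulusParams) -> WaveformSet:
    """Sham stimulation: brief ramp-up immediately followed by ramp-down at
    session start and again at session end; zero current in between."""
    n = int(round(params.duration * params.fs))
    t = np.arange(n) / params.fs
    n_ramp = int(round(params.ramp * params.fs))
    env = np.zeros(n)
    if n_ramp > 0:
        up = np.arange(n_ramp) / n_ramp
        burst = np.concatenate([up, up[::-1]])          # up then immediately down
        env[: 2 * n_ramp] = burst
        env[n - 2 * n_ramp:] = burst
    stim = _cfc_formula(t, params) * env * params.current_scale
    returns = np.tile(-stim / 4.0, (4, 1))
    return WaveformSet(stimulus=stim, returns=returns, fs=params.fs, params=params)


def analytic_extrema(
    a_fa: float = 0.2, a_fp: float = 0.8, n_grid: int = 2000
) -> tuple[float, float, float]:
    """Extrema of the un-ramped formula over independent theta/gamma phases.

    Evaluates s = (a_fa/2)(sin a + 1) sin b + a_fp sin a over a dense
    (a, b) grid in [0, 2*pi)^2 and returns (max, min, peak_to_peak).  With
    the default constants this gives (+1.0, -0.8, 1.8) -- the 1.8 mA
    peak-to-peak device setting at unit current scale.
    """
    a = np.linspace(0, 2 * np.pi, n_grid, endpoint=False)
    sa = np.sin(a)
    # for fixed theta phase a, the gamma term is maximized/minimized at sin b = +/-1
    hi = (a_fa / 2.0) * np.abs(sa + 1.0) + a_fp * sa
    lo = -(a_fa / 2.0) * np.abs(sa + 1.0) + a_fp * sa
    return float(hi.max()), float(lo.min()), float(hi.max() - lo.min())
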