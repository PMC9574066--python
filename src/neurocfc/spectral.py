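"""Morlet wavelet time-frequency analysis.

The wavelet family is parameterised by a constant ratio c = f0 / sigma_f
(default 7), so every wavelet has the same number of cycles.  For centre
frequency f0:

    sigma_f = f0 / c,   sigma_t = 1 / (2*pi*sigma_f),
    psi(t) = A * exp(i*2*pi*f0*t) * exp(-t^2 / (2*sigma_t^2)),
    A = sigma_t^(-1/2) * pi^(-1/4)        (unit energy at every scale)

At f0 = 10 Hz and c = 7 this gives a wavelet duration 2*sigma_t = 222.8 ms
and a spectral bandwidth 2*sigma_f = 2.86 Hz.  Single-trial magnitudes are
averaged across trials ("total" activity, no baseline correction); power in
microvolt-squared units is the squared averaged magnitude flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .containers import EpochsArray

__all__ = [
    "WaveletFamily",
    "PowerMap",
    "morlet_params",
    "morlet_wavelet",
    "wavelet_transform",
    "detect_individual_peak",
    "band_power_windows",
    "zscore_across_electrodes",
]


def morlet_params(f0: float, ratio: float = 7.0) -> tuple[float, float, float, float]:
    """(sigma_t [s], sigma_f [Hz], duration 2*sigma_t [ms], bandwidth 2*sigma_f [Hz])."""
    if f0 <= 0 or ratio <= 0:
        raise ValueError("f0 and ratio must be positive")
    sigma_f = f0 / ratio
    sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
    return sigma_t, sigma_f, 2.0 * sigma_t * 1e3, 2.0 * sigma_f


@dataclass(frozen=True)
class WaveletFamily:
    """Constant-ratio Morlet family over a frequency grid."""

    f0_grid: np.ndarray = field(default_factory=lambda: np.arange(3.0, 13.0 + 1e-9, 0.5))
    ratio: float = 7.0

    def __post_init__(self) -> None:
        grid = np.asarray(self.f0_grid, float)
        object.__setattr__(self, "f0_grid", grid)
        if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0):
            raise ValueError("f0_grid must be 1-D and strictly increasing")
        if grid[0] <= 0 or self.ratio <= 0:
            raise ValueError("frequencies and ratio must be positive")

    def sigma_t(self, f0: float) -> float:
        return morlet_params(f0, self.ratio)[0]


def morlet_wavelet(f0: float, fs: float, ratio: float = 7.0, n_sigma: float = 4.0) -> np.ndarray:
    """Complex Morlet wavelet sampled at fs, truncated at +/- n_sigma * sigma_t."""
    sigma_t, _, _, _ = morlet_params(f0, ratio)
    half = int(np.ceil(n_sigma * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    a = sigma_t ** -0.5 * np.pi ** -0.25
    return a * np.exp(2j * np.pi * f0 * t) * np.exp(-(t ** 2) / (2 * sigma_t ** 2))


@dataclass
class PowerMap:
    """Trial-averaged wavelet response: (channels, frequencies, times).

    ``units`` is "amplitude" (mean absolute wavelet coefficient, ~uV) or
    "power" (its square, ~uV^2).  ``edge_mask`` flags samples within
    2*sigma_t of an epoch edge at each frequency (True = contaminated).
    """

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    ch_names: list[str]
    units: str = "power"
    edge_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.ch_names), self.freqs.size, self.times.size):
            raise ValueError("values must be (channels, freqs, times)")
        if np.any(self.values < 0):
            raise ValueError("power map must be non-negative")

    def channel_index(self, name: str) -> int:
        return self.ch_names.index(name)


def wavelet_transform(
    epochs: EpochsArray, family: WaveletFamily | None = None, units: str = "power"
) -> PowerMap:
    """Convolve each trial with the Morlet family; average magnitudes across trials.

    Per-trial absolute values are averaged first (total activity); squaring
    for uV^2 units is applied to the averaged magnitude.
    """
    if units not in ("amplitude", "power"):
        raise ValueError("units must be 'amplitude' or 'power'")
    family = family or WaveletFamily()
    n_samp = epochs.n_samples
    lowest_sigma = family.sigma_t(float(family.f0_grid[0]))
    if n_samp / epochs.fs < 6 * lowest_sigma:
        raise ValueError(
            f"epoch ({n_samp / epochs.fs:.2f} s) shorter than 6*sigma_t "
            f"({6 * lowest_sigma:.2f} s) of the lowest frequency f0={family.f0_grid[0]} Hz"
        )
    out = np.zeros((epochs.n_channels, family.f0_grid.size, n_samp))
    edge = np.zeros((family.f0_grid.size, n_samp), dtype=bool)
    t_rel = np.arange(n_samp) / epochs.fs
    for fi, f0 in enumerate(family.f0_grid):
        w = morlet_wavelet(float(f0), epochs.fs, family.ratio)
        # convolve all trials/channels at once along the last axis
        coef = fftconvolve(epochs.data, w[None, None, :], mode="same", axes=2)
        out[:, fi, :] = np.abs(coef).mean(axis=0)
        two_sigma = 2 * family.sigma_t(float(f0))
        edge[fi] = (t_rel < two_sigma) | (t_rel > t_rel[-1] - two_sigma)
    if units == "power":
        out = out ** 2
    return PowerMap(out, family.f0_grid.copy(), epochs.times, list(epochs.ch_names),
                    units=units, edge_mask=edge)


@dataclass(frozen=True)
class _PeakResult:
    frequency: float
    tied: bool
    at_band_edge: bool


def detect_individual_peak(
    power: PowerMap,
    band: tuple[float, float],
    channels: list[str] | None = None,
    window: tuple[float, float] | None = None,
) -> _PeakResult:
    """Dominant frequency within a band: argmax of channel- and time-averaged
    power.  Ties break toward the lower frequency (flagged); an argmax on the
    band edge is flagged as well."""
    sel = (power.freqs >= band[0] - 1e-9) & (power.freqs <= band[1] + 1e-9)
    if not sel.any():
        raise ValueError(f"band {band} outside the frequency grid")
    ch_idx = (list(range(len(power.ch_names))) if channels is None
              else [power.channel_index(c) for c in channels])
    vals = power.values[ch_idx][:, sel, :]
    if window is not None:
        tmask = (power.times >= window[0] - 1e-9) & (power.times < window[1] - 1e-9)
        if not tmask.any():
            raise ValueError(f"window {window} outside the epoch time axis")
        vals = vals[:, :, tmask]
    spectrum = vals.mean(axis=(0, 2))
    best = int(np.argmax(spectrum))
    tied = bool(np.sum(np.isclose(spectrum, spectrum[best], rtol=0, atol=1e-12)) > 1)
    fb = power.freqs[sel]
    return _PeakResult(float(fb[best]), tied, best in (0, fb.size - 1))


def band_power_windows(
    power: PowerMap,
    band: tuple[float, float],
    windows: dict[str, tuple[float, float]],
    regions: dict[str, list[str]],
    peak_freq: float | None = None,
) -> dict[tuple[str, str], float]:
    """Mean power per (region, window) over band bins x window samples x
    region channels; with ``peak_freq`` set, only the individual-peak bin is
    used instead of the whole band."""
    if peak_freq is not None:
        fsel = np.isclose(power.freqs, peak_freq)
        if not fsel.any():
            fsel = np.zeros_like(power.freqs, bool)
            fsel[np.argmin(np.abs(power.freqs - peak_freq))] = True
    else:
        fsel = (power.freqs >= band[0] - 1e-9) & (power.freqs <= band[1] + 1e-9)
        if not fsel.any():
            raise ValueError(f"band {band} outside the frequency grid")
    out: dict[tuple[str, str], float] = {}
    for rname, chans in regions.items():
        if not chans:
            raise ValueError(f"region {rname!r} is empty")
        ch_idx = [power.channel_index(c) for c in chans]
        for wname, (t0, t1) in windows.items():
            tmask = (power.times >= t0 - 1e-9) & (power.times < t1 - 1e-9)
            if not tmask.any():
                raise ValueError(f"window {wname}={t0, t1} outside the epoch")
            out[(rname, wname)] = float(power.values[ch_idx][:, fsel][:, :, tmask].mean())
    return out


def zscore_across_electrodes(values: np.ndarray) -> np.ndarray:
    """Standardize post-minus-pre values across electrodes to mean 0, sd 1
    (sample sd, n-1 denominator)."""
    x = np.asarray(values, float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D vector of at least two electrode values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance across electrodes; Z-scores undefined")
    return (x - x.mean()) / sd
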