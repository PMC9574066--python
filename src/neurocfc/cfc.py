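"""Phase-to-power coherence cross-frequency coupling.

Coupling between the phase of a slow oscillation at f1 on one channel and
the power envelope of a fast oscillation at f2 on another channel is
quantified as the magnitude of the coherency between the raw signal x(t)
and the estimated power time course P_t(f2) of the amplitude channel:

    Coh(f1, f2) = | sum_k X_k(f1) P_k*(f1, f2) |
                  / sqrt( sum_k |X_k(f1)|^2 * sum_k |P_k(f1, f2)|^2 )

where X_k and P_k are Hanning-tapered Fourier coefficients of the k-th
data segment (L samples, half-overlapping within a trial; a whole trial
forms a single segment when it is shorter than L).  P_t(f2) itself comes
from a sliding six-cycle Hanning-tapered complex demodulation at f2
(adaptive window dT = 6/f2), squared.

Directionality is encoded by which channel supplies the phase signal and
which supplies the power envelope (e.g. Fz-phase -> Oz-amplitude versus
the reverse).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .spectral import WaveletFamily, wavelet_transform
from .containers import EpochsArray

__all__ = [
    "CFCMap",
    "power_timecourse",
    "phase_power_coherence",
    "cfc_contrast",
    "detect_troughs",
    "trough_locked_spectrogram",
]

DEFAULT_F1_GRID = np.arange(1.0, 13.0 + 1e-9, 0.5)
DEFAULT_F2_GRID = np.arange(20.0, 100.0 + 1e-9, 2.0)
SEGMENT_LEN = 2048


@dataclass
class CFCMap:
    """Coherence over the (phase f1 x amplitude f2) grid for one directed pair."""

    values: np.ndarray            # (n_f1, n_f2) in [0, 1]
    f1_grid: np.ndarray
    f2_grid: np.ndarray
    n_segments: int
    segment_len: int
    pair: tuple[str, str] = ("", "")   # (phase channel, amplitude channel)
    condition: str = ""

    def __post_init__(self) -> None:
        if self.values.shape != (self.f1_grid.size, self.f2_grid.size):
            raise ValueError("values must be (n_f1, n_f2)")
        if np.any(self.values < -1e-9) or np.any(self.values > 1 + 1e-9):
            raise ValueError("coherence values must lie in [0, 1]")
        if self.n_segments < 2:
            raise ValueError("need at least 2 segments")

    def argmax_cell(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.argmax(self.values), self.values.shape)
        return float(self.f1_grid[i]), float(self.f2_grid[j])


def power_timecourse(x: np.ndarray, fs: float, f2: float, n_cycles: float = 6.0) -> np.ndarray:
    """Instantaneous power at f2 via a sliding six-cycle Hanning-tapered
    complex demodulation, sampled on the original time axis.

    ``x`` is (..., n_samples).  The kernel length is round(n_cycles/f2 * fs);
    the taper is normalized so a unit-amplitude stationary carrier at f2
    yields power ~(1/2)*a^2 scaling, i.e. power proportional to amplitude
    squared.
    """
    x = np.asarray(x, float)
    win_len = int(round(n_cycles / f2 * fs))
    if x.shape[-1] < win_len:
        raise ValueError(
            f"trial of {x.shape[-1]} samples shorter than the {n_cycles}-cycle "
            f"window ({win_len} samples) at f2={f2} Hz"
        )
    taper = sps.windows.hann(win_len, sym=False)
    t = np.arange(win_len) / fs
    kernel = taper * np.exp(-2j * np.pi * f2 * t)
    kernel /= taper.sum() / 2.0       # unit response to a unit carrier
    coef = sps.fftconvolve(x, np.flip(kernel).reshape((1,) * (x.ndim - 1) + (-1,)),
                           mode="same", axes=-1)
    return np.abs(coef) ** 2


def _segments(trial_len: int, seg_len: int) -> list[tuple[int, int]]:
    """Half-overlapping [start, stop) segment bounds within one trial."""
    if trial_len < seg_len:
        return [(0, trial_len)]      # short trial: one full-length segment
    step = seg_len // 2
    bounds = []
    start = 0
    while start + seg_len <= trial_len:
        bounds.append((start, start + seg_len))
        start += step
    return bounds


def phase_power_coherence(
    x_trials: np.ndarray,
    y_trials: np.ndarray,
    fs: float,
    f1_grid: np.ndarray | None = None,
    f2_grid: np.ndarray | None = None,
    segment_len: int = SEGMENT_LEN,
    pair: tuple[str, str] = ("", ""),
    condition: str = "",
) -> CFCMap:
    """Coherence between the phase channel ``x`` and the f2 power envelope
    of the amplitude channel ``y`` over the (f1, f2) grid.

    ``x_trials`` and ``y_trials`` are (n_trials, n_samples).  Segments are
    taken within trials (half-overlap, ``segment_len`` samples; one segment
    per trial when trials are shorter) and pooled across trials.
    """
    x_trials = np.atleast_2d(np.asarray(x_trials, float))
    y_trials = np.atleast_2d(np.asarray(y_trials, float))
    if x_trials.shape != y_trials.shape:
        raise ValueError("phase and amplitude channels must have matching trials")
    f1_grid = DEFAULT_F1_GRID if f1_grid is None else np.asarray(f1_grid, float)
    f2_grid = DEFAULT_F2_GRID if f2_grid is None else np.asarray(f2_grid, float)
    if f1_grid.max() >= fs / 2 or f2_grid.max() >= fs / 2:
        raise ValueError("frequency grids must stay below Nyquist")
    n_trials, n_samp = x_trials.shape
    bounds = _segments(n_samp, segment_len)
    seg_list = [(ti, b0, b1) for ti in range(n_trials) for (b0, b1) in bounds]
    if len(seg_list) < 2:
        raise ValueError("fewer than 2 usable segments; provide more/longer trials")
    # one taper/exponential basis per distinct segment length
    seg_lens = sorted({b1 - b0 for _, b0, b1 in seg_list})
    basis = {}
    for sl in seg_lens:
        taper = sps.windows.hann(sl, sym=False)
        t = np.arange(sl) / fs
        basis[sl] = taper[None, :] * np.exp(-2j * np.pi * f1_grid[:, None] * t[None, :])
    values = np.zeros((f1_grid.size, f2_grid.size))
    # power envelopes for every f2 at once: (n_f2, n_trials, n_samp)
    for j, f2 in enumerate(f2_grid):
        p = power_timecourse(y_trials, fs, float(f2))
        cross = np.zeros(f1_grid.size, complex)
        auto_x = np.zeros(f1_grid.size)
        auto_p = np.zeros(f1_grid.size)
        for ti, b0, b1 in seg_list:
            e = basis[b1 - b0]
            xk = e @ x_trials[ti, b0:b1]
            pseg = p[ti, b0:b1]
            pk = e @ (pseg - pseg.mean())   # remove the DC power offset
            cross += xk * np.conj(pk)
            auto_x += np.abs(xk) ** 2
            auto_p += np.abs(pk) ** 2
        denom = np.sqrt(auto_x * auto_p)
        with np.errstate(invalid="ignore", divide="ignore"):
            coh = np.abs(cross) / denom
        values[:, j] = np.nan_to_num(coh, nan=0.0)
    return CFCMap(np.clip(values, 0.0, 1.0), f1_grid, f2_grid,
                  n_segments=len(seg_list), segment_len=segment_len,
                  pair=pair, condition=condition)


def cfc_contrast(post: CFCMap, pre: CFCMap) -> np.ndarray:
    """Elementwise post minus pre coherence; grids must match."""
    if (post.f1_grid.size != pre.f1_grid.size or post.f2_grid.size != pre.f2_grid.size
            or not np.allclose(post.f1_grid, pre.f1_grid)
            or not np.allclose(post.f2_grid, pre.f2_grid)):
        raise ValueError("CFC maps have mismatched frequency grids")
    return post.values - pre.values


def detect_troughs(
    signal: np.ndarray, fs: float, low_band: tuple[float, float] = (1.0, 4.0)
) -> np.ndarray:
    """Sample indices of troughs (local minima) of the band-passed signal.

    The trace is zero-phase band-pass filtered at ``low_band`` first; troughs
    closer than half a cycle of the band's upper edge are suppressed.
    """
    sos = sps.butter(4, low_band, btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, np.asarray(signal, float))
    min_sep = max(int(fs / low_band[1] / 2), 1)
    troughs, _ = sps.find_peaks(-filt, distance=min_sep)
    return troughs


def trough_locked_spectrogram(
    trials: np.ndarray,
    fs: float,
    low_band: tuple[float, float] = (1.0, 4.0),
    window_s: float = 1.0,
    family: WaveletFamily | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Average time-frequency map around troughs of the low-frequency rhythm.

    Each trial is narrow band-pass filtered at ``low_band``; troughs (local
    minima of the filtered trace) trigger extraction of a +/-window_s epoch
    from the unfiltered trial, which is then wavelet-decomposed and averaged
    across all troughs and trials.

    Returns (map [freqs x times], freqs, lags_s, n_troughs).
    """
    trials = np.atleast_2d(np.asarray(trials, float))
    if family is None:
        family = WaveletFamily(f0_grid=np.arange(20.0, 100.0 + 1e-9, 5.0))
    half = int(round(window_s * fs))
    if trials.shape[1] < 2 * half + 1:
        raise ValueError("trials shorter than the trough-locked window")
    snippets = []
    for tr in range(trials.shape[0]):
        troughs = detect_troughs(trials[tr], fs, low_band)
        for idx in troughs:
            if idx - half >= 0 and idx + half + 1 <= trials.shape[1]:
                snippets.append(trials[tr, idx - half: idx + half + 1])
    if not snippets:
        raise ValueError("no troughs with a complete window found")
    snip = np.stack(snippets)[:, None, :]     # troughs as trials, 1 channel
    lags = np.arange(-half, half + 1) / fs
    pos = np.zeros((1, 2))
    ep = EpochsArray(snip, fs, ["trough"], pos, tmin=float(lags[0]))
    pm = wavelet_transform(ep, family, units="power")
    return pm.values[0], family.f0_grid.copy(), lags, len(snippets)
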