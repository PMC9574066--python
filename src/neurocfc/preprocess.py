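"""EEG preprocessing: filtering, epoching, re-referencing, artifact rejection.

The chain mirrors a standard offline pipeline for a Sternberg-task recording:
0.5-Hz high-pass plus 60-Hz notch on the continuous data, segmentation from
2.5 s before to 0.5 s after the test-stimulus onset, common average
reference, and automatic rejection of trials exceeding +/-100 uV amplitude
or a 50 uV/ms gradient on any channel.  The 2-s retention period preceding
the probe is split into two 1-s halves with half-open boundaries
[-2, -1) and [-1, 0) seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .containers import EpochsArray

__all__ = [
    "filter_raw",
    "rereference_average",
    "epoch",
    "reject_artifacts",
    "split_retention",
    "RejectionReport",
]


def filter_raw(
    raw: np.ndarray,
    fs: float,
    hp_hz: float = 0.5,
    notch_hz: float = 60.0,
    notch_q: float = 30.0,
) -> np.ndarray:
    """Zero-phase 0.5-Hz high-pass and 60-Hz notch on continuous data.

    ``raw`` is (..., n_samples).  A 4th-order Butterworth high-pass and a
    second-order IIR notch (quality factor 30) are each applied
    forward-backward (zero phase, squared magnitude response).
    """
    raw = np.asarray(raw, float)
    if fs <= 2 * notch_hz:
        raise ValueError(f"fs={fs} Hz must exceed twice the notch frequency {notch_hz} Hz")
    n = raw.shape[-1]
    if n < 3 * fs / hp_hz / (2 * np.pi):  # ~3 filter time constants
        raise ValueError("record too short for the high-pass time constant")
    sos = signal.butter(4, hp_hz, btype="highpass", fs=fs, output="sos")
    out = signal.sosfiltfilt(sos, raw, axis=-1)
    b, a = signal.iirnotch(notch_hz, notch_q, fs=fs)
    return signal.filtfilt(b, a, out, axis=-1)


def rereference_average(epochs: EpochsArray) -> EpochsArray:
    """Common average reference: subtract the per-sample mean across channels."""
    if epochs.n_channels < 2:
        raise ValueError("average reference needs at least two channels")
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return epochs.copy_with(data=data)


def epoch(
    raw: np.ndarray,
    fs: float,
    event_times: np.ndarray,
    ch_names: list[str],
    positions: np.ndarray,
    window: tuple[float, float] = (-2.5, 0.5),
) -> tuple[EpochsArray, int]:
    """Segment continuous data (channels x samples) around event times.

    Trials whose window falls outside the record are dropped; the count of
    dropped events is returned alongside the epochs.  The sample at t=0 is
    the raw sample nearest each event time.
    """
    raw = np.asarray(raw, float)
    if raw.ndim != 2:
        raise ValueError("raw must be (channels, samples)")
    n_samp = int(round((window[1] - window[0]) * fs))
    offset = int(round(window[0] * fs))
    trials, dropped = [], 0
    for t_ev in np.atleast_1d(event_times):
        i0 = int(round(t_ev * fs)) + offset
        if i0 < 0 or i0 + n_samp > raw.shape[1]:
            dropped += 1
            continue
        trials.append(raw[:, i0:i0 + n_samp])
    if not trials:
        raise ValueError("no events with a complete epoch window")
    arr = EpochsArray(np.stack(trials), fs, list(ch_names), positions, tmin=window[0])
    return arr, dropped


@dataclass
class RejectionReport:
    table: pd.DataFrame        # columns: trial, rejected, reason
    rate: float

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def reject_artifacts(
    epochs: EpochsArray,
    amp_uv: float = 100.0,
    grad_uv_per_ms: float = 50.0,
) -> tuple[EpochsArray, RejectionReport]:
    """Drop trials exceeding the amplitude or gradient criterion on any channel.

    Amplitude: any sample outside [-amp_uv, +amp_uv].  Gradient: any
    adjacent-sample difference whose absolute rate exceeds
    ``grad_uv_per_ms`` after converting the sample interval to ms.
    """
    ms_per_sample = 1000.0 / epochs.fs
    amp_bad = np.abs(epochs.data).max(axis=(1, 2)) > amp_uv
    grad = np.abs(np.diff(epochs.data, axis=2)) / ms_per_sample
    grad_bad = grad.max(axis=(1, 2)) > grad_uv_per_ms
    rejected = amp_bad | grad_bad
    reasons = np.where(
        amp_bad & grad_bad, "amplitude+gradient",
        np.where(amp_bad, "amplitude", np.where(grad_bad, "gradient", "")),
    )
    table = pd.DataFrame({
        "trial": np.arange(epochs.n_trials),
        "rejected": rejected,
        "reason": reasons,
    })
    kept = epochs.copy_with(data=epochs.data[~rejected])
    report = RejectionReport(table, float(rejected.mean()))
    return kept, report


def split_retention(
    epochs: EpochsArray, retention: tuple[float, float] = (-2.0, 0.0)
) -> tuple[EpochsArray, EpochsArray]:
    """Split the retention period into its first and second 1-s halves.

    Half-open windows: first [-2, -1) s, second [-1, 0) s, so the -1.0 s
    sample belongs to the second half only.
    """
    t = epochs.times
    if t[0] > retention[0] + 1e-9 or t[-1] < retention[1] - 1.0 / epochs.fs - 1e-9:
        raise ValueError(
            f"epoch window {t[0]:.3f}..{t[-1]:.3f} s does not cover retention {retention}"
        )
    mid = 0.5 * (retention[0] + retention[1])
    return epochs.crop(retention[0], mid), epochs.crop(mid, retention[1])
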