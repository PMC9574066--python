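"""Plain-text persistence for epochs, waveforms, and tables.

Epochs are stored as a delimited numeric matrix (one row per trial-channel,
samples across columns) with a JSON sidecar holding the sampling rate,
channel names, 2-D positions and the epoch time origin, so a round trip
reconstructs the full :class:`~neurocfc.containers.EpochsArray`.
Stimulation waveforms are written as tab-separated columns
(time_s, F3_mA, Fp1_mA, Fz_mA, F7_mA, C3_mA) at six significant digits
with a JSON header sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EpochsArray
from .stimulus_design import WaveformSet

__all__ = [
    "save_epochs", "load_epochs",
    "save_waveform", "load_waveform",
    "save_behavior", "load_behavior",
]


def save_epochs(epochs: EpochsArray, prefix: str | Path) -> tuple[Path, Path]:
    prefix = Path(prefix)
    data_path = prefix.with_suffix(".tsv")
    meta_path = prefix.with_suffix(".json")
    flat = epochs.data.reshape(epochs.n_trials * epochs.n_channels, epochs.n_samples)
    np.savetxt(data_path, flat, fmt="%.6g", delimiter="\t")
    meta = {
        "fs": epochs.fs,
        "ch_names": epochs.ch_names,
        "positions_cm": epochs.positions.tolist(),
        "tmin": epochs.tmin,
        "n_trials": epochs.n_trials,
        "n_channels": epochs.n_channels,
        "n_samples": epochs.n_samples,
    }
    meta_path.write_text(json.dumps(meta, indent=1))
    return data_path, meta_path


def load_epochs(prefix: str | Path) -> EpochsArray:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    flat = np.loadtxt(prefix.with_suffix(".tsv"), delimiter="\t")
    data = flat.reshape(meta["n_trials"], meta["n_channels"], meta["n_samples"])
    return EpochsArray(
        data, meta["fs"], meta["ch_names"], np.array(meta["positions_cm"]),
        tmin=meta["tmin"],
    )


def save_waveform(ws: WaveformSet, path: str | Path) -> tuple[Path, Path]:
    path = Path(path)
    meta_path = path.with_suffix(".json")
    cols = np.column_stack([ws.times, ws.stimulus, *ws.returns])
    header = "time_s\tF3_mA\t" + "\t".join(f"{c}_mA" for c in ws.return_labels)
    np.savetxt(path, cols, fmt="%.6g", delimiter="\t", header=header, comments="")
    meta = {"fs": ws.fs, "return_labels": list(ws.return_labels)}
    if ws.params is not None:
        meta.update({
            "f_p_hz": ws.params.f_p, "f_a_hz": ws.params.f_a,
            "a_fa": ws.params.a_fa, "a_fp": ws.params.a_fp,
            "duration_s": ws.params.duration, "ramp_s": ws.params.ramp,
            "current_scale_ma": ws.params.current_scale,
        })
    meta_path.write_text(json.dumps(meta, indent=1))
    return path, meta_path


def load_waveform(path: str | Path) -> WaveformSet:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    arr = np.loadtxt(path, delimiter="\t", skiprows=1)
    return WaveformSet(
        stimulus=arr[:, 1], returns=arr[:, 2:6].T, fs=meta["fs"],
        return_labels=tuple(meta["return_labels"]),
    )


def save_behavior(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def load_behavior(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
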