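"""Core in-memory containers shared across the analysis stack.

The central object is :class:`EpochsArray`, a lightweight trials x channels x
samples container with a time axis referenced to test-stimulus onset and 2-D
scalp coordinates (cm) for each channel.  All analysis stages consume and
return these containers rather than bare arrays so that channel bookkeeping
and the epoch time axis travel with the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EpochsArray"]


@dataclass
class EpochsArray:
    """EEG epochs: ``data`` is (n_trials, n_channels, n_samples) in microvolts.

    Parameters
    ----------
    data : ndarray
        Trial-segmented EEG, microvolts.
    fs : float
        Sampling rate in Hz.
    ch_names : list of str
        Channel labels (10-20 convention).
    positions : ndarray
        (n_channels, 2) flattened scalp coordinates in centimetres.
    tmin : float
        Time of the first sample relative to test-stimulus onset, seconds.
    """

    data: np.ndarray
    fs: float
    ch_names: list[str]
    positions: np.ndarray
    tmin: float = -2.5
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (trials, channels, samples); got shape {self.data.shape}"
            )
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError(
                f"{self.data.shape[1]} data channels but {len(self.ch_names)} names"
            )
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.ch_names), 2):
            raise ValueError("positions must be (n_channels, 2) in cm")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data contains non-finite values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Time axis in seconds relative to test-stimulus onset."""
        return self.tmin + np.arange(self.n_samples) / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.ch_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage: {self.ch_names}") from None

    def get_channel(self, name: str) -> np.ndarray:
        """(n_trials, n_samples) view of one channel."""
        return self.data[:, self.channel_index(name), :]

    def copy_with(self, data: np.ndarray | None = None, **kw) -> "EpochsArray":
        return EpochsArray(
            data=self.data.copy() if data is None else data,
            fs=kw.get("fs", self.fs),
            ch_names=list(kw.get("ch_names", self.ch_names)),
            positions=kw.get("positions", self.positions).copy()
            if not isinstance(kw.get("positions", self.positions), np.ndarray)
            else np.array(kw.get("positions", self.positions)),
            tmin=kw.get("tmin", self.tmin),
            meta=dict(kw.get("meta", self.meta)),
        )

    def crop(self, t_start: float, t_stop: float) -> "EpochsArray":
        """Return the half-open time window [t_start, t_stop)."""
        t = self.times
        # round to avoid float fencepost errors at window edges
        mask = (t >= t_start - 1e-9) & (t < t_stop - 1e-9)
        if not mask.any():
            raise ValueError(f"window [{t_start}, {t_stop}) outside epoch {t[0]}..{t[-1]}")
        return self.copy_with(data=self.data[:, :, mask], tmin=float(t[mask][0]))
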