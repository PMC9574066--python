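"""Pairwise phase consistency (PPC) connectivity and nodal efficiency.

PPC is an unbiased estimate of phase synchronization across trials: the
mean cosine of the angular distance over all unordered pairs of per-trial
relative phases,

    PPC = 2 / (N (N-1)) * sum_{i<j} cos(theta_i - theta_j)

with values in [-1, 1]; 1 means all trials share the same relative phase
and 0 is the expectation for random phases.  Unlike the phase-locking
value it carries no positive bias at a finite trial count.

Graph analysis maps a channel x channel PPC matrix to a weighted graph
(negative PPC clipped to zero, proportional edge thresholding, distance =
1/weight) and summarizes each node by its nodal efficiency, the mean
inverse shortest-path distance to every other node:

    E_nodal(i) = 1/(N-1) * sum_{j != i} 1 / d_ij
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
from scipy import signal as sps

from .containers import EpochsArray

__all__ = [
    "PPCMatrix",
    "FRONTAL_SET",
    "PARIETO_OCCIPITAL_SET",
    "relative_phase",
    "ppc",
    "ppc_square_matrix",
    "ppc_contrast_matrix",
    "build_graph",
    "nodal_efficiency",
]

FRONTAL_SET = ["Fz", "F3", "F4", "FC1", "FC2"]
PARIETO_OCCIPITAL_SET = ["Pz", "P3", "P4", "Oz", "O1", "O2"]


def relative_phase(
    epochs: EpochsArray,
    freq: float,
    pairs: list[tuple[str, str]],
    window_s: float = 1.0,
) -> dict[tuple[str, str], np.ndarray]:
    """Per-trial relative phase for each channel pair at ``freq``.

    Phases come from a Hanning-tapered DFT of the first ``window_s`` of the
    epoch (caller crops to the retention half of interest beforehand), read
    at the DFT bin nearest ``freq``.  Relative phases are wrapped to
    (-pi, pi].
    """
    if freq >= epochs.fs / 2:
        raise ValueError(f"freq={freq} Hz is beyond Nyquist ({epochs.fs / 2} Hz)")
    n_win = int(round(window_s * epochs.fs))
    if n_win > epochs.n_samples:
        raise ValueError(f"{window_s}-s window exceeds the {epochs.n_samples}-sample epoch")
    seg = epochs.data[:, :, :n_win] * sps.windows.hann(n_win, sym=False)
    spec = np.fft.rfft(seg, axis=-1)
    bins = np.fft.rfftfreq(n_win, d=1.0 / epochs.fs)
    k = int(np.argmin(np.abs(bins - freq)))
    phase = np.angle(spec[:, :, k])          # (n_trials, n_channels)
    out = {}
    for a, b in pairs:
        d = phase[:, epochs.channel_index(a)] - phase[:, epochs.channel_index(b)]
        out[(a, b)] = _wrap(d)
    return out


def _wrap(angles: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(angles, float), 2 * np.pi)


def ppc(relative_phases: np.ndarray) -> float:
    """Pairwise phase consistency over N trials' relative phases.

    Direct evaluation of the pairwise-cosine double sum over all
    N(N-1)/2 unordered trial pairs.
    """
    th = np.asarray(relative_phases, float).ravel()
    n = th.size
    if n < 2:
        raise ValueError("PPC needs at least two trials")
    diff = th[:, None] - th[None, :]
    total = np.cos(diff[np.triu_indices(n, k=1)]).sum()
    return float(2.0 * total / (n * (n - 1)))


@dataclass
class PPCMatrix:
    """PPC per channel pair for one band/condition.

    ``values`` maps an unordered pair (alphabetical key order is not
    imposed; the stored key is the analysis pair order) to the PPC value;
    ``n_trials`` records N for the estimate.
    """

    values: dict[tuple[str, str], float]
    band: str
    condition: str = ""
    n_trials: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair, v in self.values.items():
            if abs(v) > 1 + 1e-9:
                raise ValueError(f"|PPC| > 1 for pair {pair}: {v}")
        if self.n_trials and self.n_trials < 2:
            raise ValueError("PPC needs N >= 2 trials")

    def get(self, a: str, b: str) -> float:
        if (a, b) in self.values:
            return self.values[(a, b)]
        return self.values[(b, a)]

    def as_vector(self, pairs: list[tuple[str, str]]) -> np.ndarray:
        return np.array([self.get(a, b) for a, b in pairs])


def ppc_square_matrix(
    epochs: EpochsArray,
    freq: float,
    channels: list[str] | None = None,
    window_s: float = 1.0,
) -> tuple[np.ndarray, list[str]]:
    """Full symmetric channel x channel PPC matrix at ``freq``.

    Diagonal entries are 1 (a channel is perfectly consistent with itself).
    """
    channels = list(epochs.ch_names) if channels is None else list(channels)
    pairs = list(combinations(channels, 2))
    phases = relative_phase(epochs, freq, pairs, window_s=window_s)
    n = len(channels)
    mat = np.eye(n)
    idx = {c: i for i, c in enumerate(channels)}
    for (a, b), th in phases.items():
        v = ppc(th)
        mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = v
    return mat, channels


def ppc_contrast_matrix(
    pre: list[PPCMatrix],
    post: list[PPCMatrix],
    pairs: list[tuple[str, str]],
    q: float = 0.05,
):
    """Per-pair post-minus-pre PPC change across subjects with Wilcoxon + FDR.

    ``pre`` and ``post`` hold one :class:`PPCMatrix` per subject (matched
    order).  Returns a DataFrame with the mean difference per pair, the
    Wilcoxon signed-rank p-value across subjects, and the BH-FDR
    significance flag at level ``q``; ``direction`` is +1 for an increase
    in phase locking.
    """
    import pandas as pd
    from .stats import fdr_bh, wilcoxon_signed_rank

    if len(pre) != len(post):
        raise ValueError("pre and post must hold the same subjects")
    pre_vals = np.array([m.as_vector(pairs) for m in pre])     # (n_sub, n_pairs)
    post_vals = np.array([m.as_vector(pairs) for m in post])
    diff = post_vals - pre_vals
    pvals = np.ones(len(pairs))
    for k in range(len(pairs)):
        if np.all(diff[:, k] == 0):
            pvals[k] = 1.0
        else:
            _, pvals[k] = wilcoxon_signed_rank(pre_vals[:, k], post_vals[:, k])
    sig = fdr_bh(pvals, q=q)
    return pd.DataFrame({
        "pair": [f"{a}-{b}" for a, b in pairs],
        "diff": diff.mean(axis=0),
        "p": pvals,
        "significant": sig,
        "direction": np.sign(diff.mean(axis=0)).astype(int),
    })


def build_graph(
    ppc_square: np.ndarray,
    channels: list[str],
    threshold_prop: float = 0.3,
) -> nx.Graph:
    """Weighted graph from a symmetric PPC matrix.

    Negative PPC values are clipped to zero; edges are ranked by weight and
    only the strongest ``threshold_prop`` fraction kept (proportional
    thresholding, so graph density is matched across conditions); each
    surviving edge carries distance = 1/weight.
    """
    w = np.asarray(ppc_square, float)
    n = len(channels)
    if w.shape != (n, n) or not np.allclose(w, w.T, atol=1e-9):
        raise ValueError("need a square symmetric PPC matrix over the channels")
    if not 0 < threshold_prop <= 1:
        raise ValueError("threshold_prop must lie in (0, 1]")
    g = nx.Graph()
    g.add_nodes_from(channels)
    iu = np.triu_indices(n, k=1)
    weights = np.clip(w[iu], 0.0, None)
    positive = weights > 0
    n_keep = int(round(threshold_prop * positive.sum()))
    if n_keep == 0:
        g.graph["isolated"] = True
        return g
    order = np.argsort(weights)[::-1][:n_keep]
    for k in order:
        i, j = iu[0][k], iu[1][k]
        if weights[k] > 0:
            g.add_edge(channels[i], channels[j],
                       weight=float(weights[k]), distance=1.0 / float(weights[k]))
    g.graph["isolated"] = g.number_of_edges() == 0
    return g


def nodal_efficiency(graph: nx.Graph) -> dict[str, float]:
    """Nodal efficiency per channel: mean inverse shortest-path distance.

    Path length is the sum of edge distances; unreachable nodes contribute
    zero (the 1/infinity convention), so an isolated node scores 0.
    """
    nodes = list(graph.nodes)
    n = len(nodes)
    if n < 2:
        return {v: 0.0 for v in nodes}
    eff = {}
    for src in nodes:
        lengths = nx.single_source_dijkstra_path_length(graph, src, weight="distance")
        total = sum(1.0 / d for v, d in lengths.items() if v != src and d > 0)
        eff[src] = total / (n - 1)
    return eff
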