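"""Behavioral normalization, rank tests, FDR, and cluster-based permutation tests.

Two cluster procedures are provided:

* :func:`cluster_permutation_map` — unpaired, one-sided comparison of two
  groups of (f1 x f2) difference maps.  Cells are scored with a rank-sum z
  statistic, thresholded at the cluster-defining alpha, clustered under
  4-neighbourhood grid adjacency, and cluster size is referred to the
  permutation distribution of the maximum cluster size under group-label
  exchange (the observed labelling counts as one permutation sample, so
  the smallest attainable p is 1/n_permutations).

* :func:`cluster_permutation_channels` — paired pre/post comparison of
  per-channel values (e.g. nodal efficiency), permuting the pre/post
  assignment within each participant.  Channel adjacency is spatial
  (< 6 cm); the cluster-defining threshold is the 2.5th/97.5th quantile of
  each channel's own permutation distribution (two-tailed at alpha 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import ndimage, stats as sst
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClusterTestResult",
    "normalize_behavior",
    "rt_filter_95ci",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "fdr_bh",
    "cluster_permutation_map",
    "cluster_permutation_channels",
]


def normalize_behavior(pre: np.ndarray, post: np.ndarray) -> np.ndarray:
    """Per-subject normalized change: (post - pre) / pre."""
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if np.any(pre <= 0):
        raise ValueError("pre-treatment values must be positive for normalization")
    return (post - pre) / pre


def rt_filter_95ci(rts: np.ndarray, min_n: int = 5) -> np.ndarray:
    """Keep reaction times inside the subject's 95% interval (mean +/- 1.96 sd).

    A single pass; with fewer than ``min_n`` observations the data pass
    through unchanged with a warning.
    """
    rts = np.asarray(rts, float)
    if rts.size < min_n:
        warnings.warn(f"only {rts.size} RTs; 95% filtering skipped", stacklevel=2)
        return rts.copy()
    mu, sd = rts.mean(), rts.std(ddof=1)
    keep = np.abs(rts - mu) <= 1.96 * sd
    return rts[keep]


def mann_whitney_u(a: np.ndarray, b: np.ndarray, alternative: str = "two-sided"):
    """Independent-sample Mann-Whitney U (exact for n <= 25 without ties)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    method = "exact" if max(a.size, b.size) <= 25 else "asymptotic"
    try:
        res = sst.mannwhitneyu(a, b, alternative=alternative, method=method)
    except ValueError:       # ties force the normal approximation
        res = sst.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(pre: np.ndarray, post: np.ndarray, alternative: str = "two-sided"):
    """Paired Wilcoxon signed-rank test on post - pre."""
    pre, post = np.asarray(pre, float), np.asarray(post, float)
    if pre.shape != post.shape:
        raise ValueError("paired samples must have matching lengths")
    d = post - pre
    if np.all(d == 0):
        raise ValueError("all paired differences are zero; Wilcoxon test degenerate")
    method = "exact" if pre.size <= 25 and not np.any(d == 0) and np.unique(np.abs(d)).size == d.size else "approx"
    res = sst.wilcoxon(post, pre, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def fdr_bh(pvalues: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level q."""
    p = np.asarray(pvalues, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, bool)
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


@dataclass
class ClusterTestResult:
    clusters: list[list]               # grid cells (i, j) or channel names
    cluster_sizes: list[int]
    p_values: list[float]
    mask: np.ndarray                   # significance mask over the map/channels
    n_permutations: int
    sided: str
    pairing: str
    exact_enumeration: bool = False
    cluster_signs: list[int] = field(default_factory=list)

    @property
    def significant(self) -> list[int]:
        return [k for k, p in enumerate(self.p_values) if p < self._alpha]

    _alpha: float = 0.05


def _ranksum_z_maps(stacked: np.ndarray, n_a: int, picks: np.ndarray) -> np.ndarray:
    """Vectorized rank-sum z over grid cells for many permutations.

    ``stacked`` is (n_subjects, ...) pooled data; ``picks`` is
    (n_perm, n_a) index array selecting group-A members per permutation.
    Ranks per cell are fixed across permutations, so each permutation is a
    sum over selected subjects' ranks.
    """
    n = stacked.shape[0]
    flat = stacked.reshape(n, -1)
    ranks = sst.rankdata(flat, axis=0)
    mu = n_a * (n + 1) / 2.0
    # tie-corrected variance of the rank sum
    var = n_a * (n - n_a) * (n + 1) / 12.0
    tie_term = np.zeros(flat.shape[1])
    for c in range(flat.shape[1]):
        _, counts = np.unique(flat[:, c], return_counts=True)
        t = counts[counts > 1]
        if t.size:
            tie_term[c] = (t ** 3 - t).sum()
    var = var - n_a * (n - n_a) * tie_term / (12.0 * n * (n - 1))
    var = np.maximum(var, 1e-12)
    r_sum = ranks[picks].sum(axis=1)            # (n_perm, n_cells)
    return ((r_sum - mu) / np.sqrt(var)).reshape((picks.shape[0],) + stacked.shape[1:])


def _grid_clusters(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """4-neighbourhood connected components of a 2-D boolean mask."""
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    return ndimage.label(mask, structure=structure)


def cluster_permutation_map(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_perm: int = 5000,
    cell_alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    sided: str = "less",
    rng: np.random.Generator | int | None = None,
) -> ClusterTestResult:
    """Cluster-size permutation test between two groups of (f1 x f2) maps.

    ``sided="less"`` tests group A < group B (one-sided); ``"greater"`` the
    reverse.  The observed labelling is included among the ``n_perm``
    permutation samples.  When ``n_perm`` meets or exceeds the number of
    distinct relabelings, all of them are enumerated exactly instead.
    """
    group_a = np.asarray(group_a, float)
    group_b = np.asarray(group_b, float)
    if group_a.ndim != 3 or group_b.ndim != 3 or group_a.shape[1:] != group_b.shape[1:]:
        raise ValueError("groups must be (subjects, n_f1, n_f2) on a shared grid")
    if group_a.shape[0] < 2 or group_b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if sided not in ("less", "greater"):
        raise ValueError("sided must be 'less' or 'greater'")
    rng = np.random.default_rng(rng)
    n_a, n_b = group_a.shape[0], group_b.shape[0]
    n = n_a + n_b
    stacked = np.concatenate([group_a, group_b], axis=0)

    n_exact = comb(n, n_a)
    exact = n_perm >= n_exact
    if exact:
        picks = np.array(list(combinations(range(n), n_a)))
    else:
        observed = np.arange(n_a)
        perms = [observed]
        for _ in range(n_perm - 1):
            perms.append(rng.permutation(n)[:n_a])
        picks = np.array(perms)
    z = _ranksum_z_maps(stacked, n_a, picks)
    z_crit = sst.norm.ppf(cell_alpha)           # one-sided threshold
    supra = z < z_crit if sided == "less" else z > -z_crit

    max_sizes = np.zeros(picks.shape[0], dtype=int)
    for k in range(picks.shape[0]):
        labels, n_lab = _grid_clusters(supra[k])
        if n_lab:
            max_sizes[k] = np.bincount(labels.ravel())[1:].max()
    obs_labels, n_obs = _grid_clusters(supra[0])
    clusters, sizes, pvals = [], [], []
    mask = np.zeros(group_a.shape[1:], bool)
    total = picks.shape[0]
    for lab in range(1, n_obs + 1):
        cells = np.argwhere(obs_labels == lab)
        size = len(cells)
        p = float(np.mean(max_sizes >= size))
        clusters.append([tuple(c) for c in cells])
        sizes.append(size)
        pvals.append(p)
        if p < cluster_alpha:
            mask[obs_labels == lab] = True
    res = ClusterTestResult(clusters, sizes, pvals, mask, total, sided,
                            pairing="unpaired", exact_enumeration=exact)
    res._alpha = cluster_alpha
    return res


def _channel_clusters(mask: np.ndarray, adjacency: np.ndarray) -> list[np.ndarray]:
    """Connected components of supra-threshold channels under adjacency."""
    idx = np.flatnonzero(mask)
    unvisited = set(idx.tolist())
    comps = []
    while unvisited:
        stack = [unvisited.pop()]
        comp = []
        while stack:
            v = stack.pop()
            comp.append(v)
            nbrs = np.flatnonzero(adjacency[v]) if adjacency.ndim == 2 else []
            for u in nbrs:
                if u in unvisited:
                    unvisited.remove(u)
                    stack.append(u)
        comps.append(np.array(sorted(comp)))
    return comps


def cluster_permutation_channels(
    pre: np.ndarray,
    post: np.ndarray,
    positions: np.ndarray,
    ch_names: list[str] | None = None,
    adjacency_cm: float = 6.0,
    n_perm: int = 5000,
    cluster_alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> ClusterTestResult:
    """Paired spatial cluster permutation test on per-channel values.

    ``pre`` and ``post`` are (n_subjects, n_channels).  The per-channel
    statistic is the mean post-pre difference; its null distribution comes
    from random within-subject pre/post swaps (sign flips of each subject's
    difference).  Channels beyond the 2.5th/97.5th quantile of their own
    permutation distribution define clusters under < ``adjacency_cm``
    spatial adjacency; cluster size is referred to the max-cluster null.
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.shape != post.shape or pre.ndim != 2:
        raise ValueError("pre and post must be matching (subjects, channels) arrays")
    n_sub, n_ch = pre.shape
    positions = np.asarray(positions, float)
    if positions.shape != (n_ch, 2):
        raise ValueError("positions must be (n_channels, 2) in cm")
    from .montage import adjacency_matrix
    adjacency = adjacency_matrix(positions, threshold_cm=adjacency_cm)
    if not adjacency.any():
        raise ValueError(f"no channel pairs closer than {adjacency_cm} cm; adjacency empty")
    rng = np.random.default_rng(rng)
    diff = post - pre
    n_exact = 2 ** n_sub
    exact = n_perm >= n_exact
    if exact:
        signs = np.array([[1 if (k >> s) & 1 else -1 for s in range(n_sub)]
                          for k in range(n_exact)])
        signs[0] = 1
    else:
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
        signs[0] = 1.0                      # observed labelling included
    stats_perm = (signs[:, :, None] * diff[None, :, :]).mean(axis=1)  # (n_perm, n_ch)
    lo = np.quantile(stats_perm, 0.025, axis=0)
    hi = np.quantile(stats_perm, 0.975, axis=0)
    supra_pos = stats_perm > hi[None, :]
    supra_neg = stats_perm < lo[None, :]
    total = stats_perm.shape[0]
    max_sizes = np.zeros(total, dtype=int)
    for k in range(total):
        best = 0
        for m in (supra_pos[k], supra_neg[k]):
            if m.any():
                comps = _channel_clusters(m, adjacency)
                best = max(best, max(len(c) for c in comps))
        max_sizes[k] = best
    names = ch_names if ch_names is not None else [str(i) for i in range(n_ch)]
    clusters, sizes, pvals, signs_out = [], [], [], []
    mask = np.zeros(n_ch, bool)
    for sign, m in ((1, supra_pos[0]), (-1, supra_neg[0])):
        if not m.any():
            continue
        for comp in _channel_clusters(m, adjacency):
            size = len(comp)
            p = float(np.mean(max_sizes >= size))
            clusters.append([names[i] for i in comp])
            sizes.append(size)
            pvals.append(p)
            signs_out.append(sign)
            if p < cluster_alpha:
                mask[comp] = True
    res = ClusterTestResult(clusters, sizes, pvals, mask, total, "two-sided",
                            pairing="paired", exact_enumeration=exact,
                            cluster_signs=signs_out)
    res._alpha = cluster_alpha
    return res
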