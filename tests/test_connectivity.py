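"""PPC, graph construction, nodal efficiency."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neurocfc.connectivity_network import (
    build_graph,
    nodal_efficiency,
    ppc,
    ppc_contrast_matrix,
    ppc_square_matrix,
    relative_phase,
    PPCMatrix,
)
from neurocfc.containers import EpochsArray
from neurocfc.montage import standard_positions


def _epochs(data, fs=500.0):
    names, pos = standard_positions()
    return EpochsArray(data, fs, names[: data.shape[1]], pos[: data.shape[1]], tmin=0.0)


class TestPPC:
    def test_identical_phases_give_one(self):
        assert ppc(np.full(10, 0.7)) == pytest.approx(1.0, abs=1e-12)

    def test_worked_three_trial_set(self):
        # pairs: cos(0) + cos(pi) + cos(pi) = -1, over 3 pairs
        assert ppc(np.array([0.0, 0.0, np.pi])) == pytest.approx(-1.0 / 3.0, abs=1e-12)

    def test_uniform_phases_near_zero(self):
        rng = np.random.default_rng(1)
        th = rng.uniform(-np.pi, np.pi, 300)
        n_pairs = th.size * (th.size - 1) / 2
        assert abs(ppc(th)) < 3.0 / np.sqrt(n_pairs)

    def test_fewer_than_two_trials_errors(self):
        with pytest.raises(ValueError, match="two"):
            ppc(np.array([0.3]))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(2, 40), st.integers(0, 10_000))
    def test_pairwise_sum_equals_unbiased_closed_form(self, n, seed):
        # PPC == (N R^2 - 1)/(N - 1) with R the mean resultant length
        th = np.random.default_rng(seed).uniform(-np.pi, np.pi, n)
        r = np.abs(np.exp(1j * th).mean())
        closed = (n * r**2 - 1.0) / (n - 1.0)
        assert ppc(th) == pytest.approx(closed, abs=1e-12)


class TestRelativePhase:
    fs = 500.0

    def _two_channel(self, delay_s=0.0, freq=5.0, n_trials=4):
        t = np.arange(int(2 * self.fs)) / self.fs
        a = np.sin(2 * np.pi * freq * t)
        b = np.sin(2 * np.pi * freq * (t - delay_s))
        data = np.stack([np.stack([a, b])] * n_trials)
        return _epochs(data)

    def test_identical_signals_zero_phase(self):
        ep = self._two_channel(0.0)
        ph = relative_phase(ep, 5.0, [(ep.ch_names[0], ep.ch_names[1])])
        assert np.abs(list(ph.values())[0]).max() < 1e-9

    def test_quarter_period_delay_is_half_pi(self):
        freq = 5.0
        ep = self._two_channel(delay_s=0.25 / freq, freq=freq)
        ph = list(relative_phase(ep, freq, [(ep.ch_names[0], ep.ch_names[1])]).values())[0]
        assert np.allclose(np.abs(ph), np.pi / 2, atol=0.05)

    def test_wrapping_into_interval(self):
        from neurocfc.connectivity_network import _wrap
        d = _wrap(np.array([3.0 - (-3.0)]))       # 6 rad wraps to 6 - 2*pi
        assert -np.pi < d[0] <= np.pi
        assert d[0] == pytest.approx(6.0 - 2 * np.pi)

    def test_beyond_nyquist_errors(self):
        ep = self._two_channel()
        with pytest.raises(ValueError, match="Nyquist"):
            relative_phase(ep, 300.0, [(ep.ch_names[0], ep.ch_names[1])])


class TestGraphAndEfficiency:
    def test_full_ppc_gives_complete_unit_distance_graph(self):
        chans = ["a", "b", "c", "d"]
        g = build_graph(np.ones((4, 4)), chans, threshold_prop=1.0)
        assert g.number_of_edges() == 6
        assert all(d["distance"] == 1.0 for _, _, d in g.edges(data=True))
        eff = nodal_efficiency(g)
        assert all(v == pytest.approx(1.0) for v in eff.values())

    def test_negative_ppc_edge_absent(self):
        mat = np.ones((3, 3))
        mat[0, 1] = mat[1, 0] = -0.4
        g = build_graph(mat, ["a", "b", "c"], threshold_prop=1.0)
        assert not g.has_edge("a", "b")

    def test_proportional_threshold_keeps_three_of_ten(self):
        rng = np.random.default_rng(0)
        n = 5                                  # 10 unordered pairs
        w = rng.uniform(0.1, 1.0, (n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        g = build_graph(w, list("abcde"), threshold_prop=0.3)
        assert g.number_of_edges() == 3

    def test_path_graph_worked_example(self):
        mat = np.zeros((4, 4))
        for i in range(3):
            mat[i, i + 1] = mat[i + 1, i] = 1.0
        g = build_graph(mat, list("abcd"), threshold_prop=1.0)
        eff = nodal_efficiency(g)
        assert eff["a"] == pytest.approx(11.0 / 18.0)
        assert eff["b"] == pytest.approx(5.0 / 6.0)

    def test_isolated_node_zero(self):
        mat = np.zeros((3, 3))
        mat[0, 1] = mat[1, 0] = 0.8
        g = build_graph(mat, list("abc"), threshold_prop=1.0)
        assert nodal_efficiency(g)["c"] == 0.0

    def test_matches_brute_force_shortest_paths(self, rng):
        # independent oracle: Floyd-Warshall on the distance matrix
        for trial in range(10):
            n = int(rng.integers(3, 9))
            w = rng.uniform(0.0, 1.0, (n, n))
            w = (w + w.T) / 2
            w[rng.random((n, n)) < 0.3] = 0.0
            w = np.minimum(w, w.T)
            np.fill_diagonal(w, 0.0)
            chans = [f"c{i}" for i in range(n)]
            g = build_graph(w, chans, threshold_prop=1.0)
            d = np.full((n, n), np.inf)
            np.fill_diagonal(d, 0.0)
            for i in range(n):
                for j in range(n):
                    if i != j and w[i, j] > 0:
                        d[i, j] = 1.0 / w[i, j]
            for k in range(n):
                for i in range(n):
                    for j in range(n):
                        d[i, j] = min(d[i, j], d[i, k] + d[k, j])
            expected = {
                chans[i]: float(np.sum([1.0 / d[i, j] for j in range(n)
                                        if j != i and np.isfinite(d[i, j])]) / (n - 1))
                for i in range(n)
            }
            eff = nodal_efficiency(g)
            for c in chans:
                assert eff[c] == pytest.approx(expected[c], abs=1e-9)

    def test_adding_edge_never_decreases_efficiency(self, rng):
        n = 6
        w = rng.uniform(0.2, 1.0, (n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        mask = np.triu(rng.random((n, n)) < 0.5, k=1)
        w_sparse = np.where(mask | mask.T, w, 0.0)
        chans = [f"c{i}" for i in range(n)]
        base = nodal_efficiency(build_graph(w_sparse, chans, threshold_prop=1.0))
        # add one absent edge
        absent = np.argwhere(~(mask | mask.T) & ~np.eye(n, dtype=bool))
        i, j = absent[0]
        w_plus = w_sparse.copy()
        w_plus[i, j] = w_plus[j, i] = w[i, j]
        more = nodal_efficiency(build_graph(w_plus, chans, threshold_prop=1.0))
        for c in chans:
            assert more[c] >= base[c] - 1e-12


class TestPPCContrast:
    def _matrix(self, vals, pairs, cond):
        return PPCMatrix(dict(zip(pairs, vals)), band="theta", condition=cond, n_trials=30)

    def test_no_change_no_significance(self, rng):
        pairs = [("Fz", "Pz"), ("F3", "Oz"), ("F4", "O1")]
        pre, post = [], []
        for s in range(10):
            v = rng.uniform(0.1, 0.6, 3)
            pre.append(self._matrix(v, pairs, "pre"))
            post.append(self._matrix(v, pairs, "post"))
        out = ppc_contrast_matrix(pre, post, pairs)
        assert not out["significant"].any()

    def test_planted_increase_flagged_positive(self, rng):
        pairs = [(a, b) for a in ("Fz", "F3") for b in ("Pz", "Oz", "O1")]
        boosted = pairs[:3]
        pre, post = [], []
        for s in range(12):
            v = rng.uniform(0.1, 0.3, len(pairs))
            pre.append(self._matrix(v, pairs, "pre"))
            v2 = v.copy()
            for k, p in enumerate(pairs):
                if p in boosted:
                    v2[k] = v[k] + rng.uniform(0.3, 0.4)
                else:
                    v2[k] = v[k] + rng.normal(0.0, 0.01)
            post.append(self._matrix(v2, pairs, "post"))
        out = ppc_contrast_matrix(pre, post, pairs)
        flagged = set(out.loc[out["significant"], "pair"])
        assert {f"{a}-{b}" for a, b in boosted} <= flagged
        assert (out.loc[out["significant"], "direction"] >= 0).all()


class TestHubRecovery:
    def test_hub_channel_has_top_efficiency(self):
        from neurocfc.synthetic_data import SimulationConfig, generate_epochs
        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(n_trials=30, n_channels=12, phase_jitter_sd=1.0,
                                   hub_channel="F3", noise_sd=3.0, seed=seed)
            epochs, truth = generate_epochs(cfg)
            second = epochs.crop(-1.0, 0.0)
            mat, chans = ppc_square_matrix(second, cfg.theta_freq)
            eff = nodal_efficiency(build_graph(mat, chans))
            hits += max(eff, key=eff.get) == truth.hub_channel
        assert hits >= 9
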