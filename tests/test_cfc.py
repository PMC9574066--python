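"""Phase-to-power coherence and trough-locked spectrograms."""

import numpy as np
import pytest

from neurocfc.cfc import (
    cfc_contrast,
    detect_troughs,
    phase_power_coherence,
    power_timecourse,
    trough_locked_spectrogram,
)

FS = 250.0


class TestPowerTimecourse:
    def test_stationary_carrier_constant_power(self):
        t = np.arange(int(4 * FS)) / FS
        x = np.sin(2 * np.pi * 40.0 * t)
        p = power_timecourse(x, FS, 40.0)
        core = p[int(0.5 * FS): -int(0.5 * FS)]
        assert np.ptp(core) / core.mean() < 0.05

    def test_amplitude_step_quadruples_power(self):
        t = np.arange(int(8 * FS)) / FS
        amp = np.where(t < 4.0, 1.0, 2.0)
        x = amp * np.sin(2 * np.pi * 40.0 * t)
        p = power_timecourse(x, FS, 40.0)
        before = p[int(1 * FS): int(3 * FS)].mean()
        after = p[int(5 * FS): int(7 * FS)].mean()
        assert after / before == pytest.approx(4.0, rel=0.05)

    def test_zero_signal_zero_power(self):
        assert np.abs(power_timecourse(np.zeros(1000), FS, 40.0)).max() == 0.0

    def test_trial_too_short_errors(self):
        with pytest.raises(ValueError, match="6"):
            power_timecourse(np.zeros(10), FS, 20.0)


class TestPhasePowerCoherence:
    def _coupled_trials(self, f1, f2, n_trials=6, dur=8.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(int(dur * FS)) / FS
        xs, ys = [], []
        for _ in range(n_trials):
            ph = rng.uniform(0, 2 * np.pi)
            xs.append(np.sin(2 * np.pi * f1 * t + ph))
            ys.append(np.sin(2 * np.pi * f2 * t) * (1 + np.sin(2 * np.pi * f1 * t + ph)))
        return np.array(xs), np.array(ys)

    def test_perfect_phase_power_locking(self):
        x, y = self._coupled_trials(5.0, 60.0)
        cm = phase_power_coherence(x, y, FS, np.arange(2.0, 9.0),
                                   np.arange(40.0, 90.0, 10.0), segment_len=512)
        i = list(cm.f1_grid).index(5.0)
        j = list(cm.f2_grid).index(60.0)
        assert cm.values[i, j] > 0.95

    def test_values_bounded(self, rng):
        x = rng.standard_normal((5, 600))
        y = rng.standard_normal((5, 600))
        cm = phase_power_coherence(x, y, FS, np.arange(2.0, 9.0),
                                   np.array([40.0, 60.0]), segment_len=512)
        assert np.all(cm.values >= 0.0) and np.all(cm.values <= 1.0)

    def test_white_noise_bias_matches_segment_count(self):
        # with M independent segments, E[coherence^2] ~= 1/M for unrelated inputs
        M = 8
        sq = []
        for run in range(40):
            rg = np.random.default_rng(500 + run)
            x = rg.standard_normal((M, 400))
            y = rg.standard_normal((M, 400))
            cm = phase_power_coherence(x, y, FS, np.array([4.0, 6.0]),
                                       np.array([50.0]), segment_len=512)
            sq.append(float((cm.values ** 2).mean()))
        sq = np.array(sq)
        mc_sd = sq.std(ddof=1) / np.sqrt(sq.size)
        assert abs(sq.mean() - 1.0 / M) < max(2 * mc_sd, 0.3 / M)

    def test_amplitude_rescaling_invariance(self):
        x, y = self._coupled_trials(5.0, 60.0, seed=3)
        f1g, f2g = np.array([4.0, 5.0]), np.array([50.0, 60.0])
        base = phase_power_coherence(x, y, FS, f1g, f2g, segment_len=512)
        scaled = phase_power_coherence(7.3 * x, 0.2 * y, FS, f1g, f2g, segment_len=512)
        assert np.allclose(base.values, scaled.values, atol=1e-9)

    def test_mismatched_trials_error(self):
        with pytest.raises(ValueError, match="matching"):
            phase_power_coherence(np.zeros((2, 600)), np.zeros((3, 600)), FS,
                                  np.array([5.0]), np.array([50.0]))

    def test_single_short_trial_rejected(self):
        with pytest.raises(ValueError, match="segments"):
            phase_power_coherence(np.zeros((1, 300)), np.zeros((1, 300)), FS,
                                  np.array([5.0]), np.array([50.0]), segment_len=512)


class TestContrast:
    def _map(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((4, 600))
        return phase_power_coherence(x, rng.standard_normal((4, 600)), FS,
                                     np.array([4.0, 5.0]), np.array([40.0, 50.0]),
                                     segment_len=512)

    def test_identical_maps_give_zero(self):
        m = self._map(0)
        assert np.abs(cfc_contrast(m, m)).max() == 0.0

    def test_antisymmetry(self):
        a, b = self._map(1), self._map(2)
        assert np.allclose(cfc_contrast(a, b), -cfc_contrast(b, a))

    def test_grid_mismatch_errors(self):
        a = self._map(1)
        rng = np.random.default_rng(3)
        b = phase_power_coherence(rng.standard_normal((4, 600)),
                                  rng.standard_normal((4, 600)), FS,
                                  np.array([4.0, 6.0]), np.array([40.0, 50.0]),
                                  segment_len=512)
        with pytest.raises(ValueError, match="grid"):
            cfc_contrast(a, b)

    def test_planted_post_only_coupling_drives_argmax(self):
        rng = np.random.default_rng(9)
        t = np.arange(int(8 * FS)) / FS
        f1, f2 = 2.0, 60.0
        xs, ys_pre, ys_post = [], [], []
        for _ in range(6):
            ph = rng.uniform(0, 2 * np.pi)
            xs.append(np.sin(2 * np.pi * f1 * t + ph) + 0.1 * rng.standard_normal(t.size))
            carrier = np.sin(2 * np.pi * f2 * t)
            ys_pre.append(carrier + 1.0 * rng.standard_normal(t.size))
            ys_post.append(carrier * (1 + np.sin(2 * np.pi * f1 * t + ph))
                           + 1.0 * rng.standard_normal(t.size))
        f1g = np.array([1.0, 2.0, 3.0, 5.0])
        f2g = np.array([40.0, 60.0, 80.0])
        x = np.array(xs)
        pre = phase_power_coherence(x, np.array(ys_pre), FS, f1g, f2g, segment_len=512)
        post = phase_power_coherence(x, np.array(ys_post), FS, f1g, f2g, segment_len=512)
        diff = cfc_contrast(post, pre)
        i, j = np.unravel_index(np.argmax(diff), diff.shape)
        assert (f1g[i], f2g[j]) == (2.0, 60.0)


class TestTroughLocking:
    def test_trough_count_on_pure_sinusoid(self):
        f = 2.5
        dur = 8.0
        t = np.arange(int(dur * FS)) / FS
        x = np.sin(2 * np.pi * f * t)
        troughs = detect_troughs(x, FS, (1.0, 4.0))
        assert abs(len(troughs) - dur * f) <= 1

    def test_gamma_bursts_at_delta_troughs_peak_at_lag_zero(self):
        rng = np.random.default_rng(4)
        t = np.arange(int(6 * FS)) / FS
        f_low = 2.5
        trials = []
        for _ in range(8):
            slow = np.sin(2 * np.pi * f_low * t)
            env = (1 - slow) / 2          # bursts at troughs of the slow rhythm
            trials.append(slow + env * np.sin(2 * np.pi * 60.0 * t)
                          + 0.1 * rng.standard_normal(t.size))
        tf, freqs, lags, n = trough_locked_spectrogram(
            np.array(trials), FS, low_band=(1.0, 4.0), window_s=1.0)
        assert n > 20
        gamma_rows = (freqs >= 50) & (freqs <= 70)
        profile = tf[gamma_rows].mean(axis=0)
        lag0 = np.argmin(np.abs(lags))
        # gamma power concentrates at the trough (lag 0) vs the flanking half-cycles
        flank = profile[np.abs(np.abs(lags) - 0.5 / f_low) < 0.05]
        assert profile[lag0] > 1.5 * flank.mean()

    def test_white_noise_has_no_lag_zero_structure(self, rng):
        trials = rng.standard_normal((8, int(6 * FS)))
        tf, freqs, lags, n = trough_locked_spectrogram(trials, FS)
        profile = tf.mean(axis=0)
        core = (np.abs(lags) < 0.8)
        assert np.ptp(profile[core]) / profile[core].mean() < 0.5
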