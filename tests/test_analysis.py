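import numpy as np
import pytest

from ephapsim import (baseline_difference, compute_phase_stats, halfwave_stats,
                      phase_correlation, phase_fold, psth,
                      relative_rate_change)


class TestPsth:
    def test_empty_trains_all_zero(self):
        h = psth([], 10.0, 1000.0)
        assert h.shape == (100,) and not h.any()

    def test_single_spike_bin_assignment(self):
        h = psth([np.array([325.0])], 10.0, 1000.0)
        assert h[32] == 1 and h.sum() == 1  # [320, 330)

    def test_total_count_conserved(self, rng):
        trains = [np.sort(rng.uniform(0, 1000.0, rng.integers(0, 50)))
                  for _ in range(20)]
        h = psth(trains, 10.0, 1000.0)
        assert h.sum() == sum(len(t) for t in trains)

    def test_non_divisible_bin_rejected(self):
        with pytest.raises(ValueError):
            psth([], 3.0, 1000.0)


class TestBaselineDifference:
    def test_identical_inputs_zero(self):
        h = np.arange(10)
        assert not baseline_difference(h, h).any()

    def test_single_bin_increment(self):
        base = np.zeros(10, dtype=int)
        cond = base.copy()
        cond[3] = 1
        d = baseline_difference(cond, base)
        assert d[3] == 1 and d.sum() == 1

    def test_sum_is_count_difference(self, rng):
        a = rng.integers(0, 5, 100)
        b = rng.integers(0, 5, 100)
        assert baseline_difference(a, b).sum() == a.sum() - b.sum()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            baseline_difference(np.zeros(10), np.zeros(11))


class TestPhaseFold:
    def test_single_spike_folds_to_phase_bin(self):
        h = psth([np.array([325.0])], 10.0, 1000.0)
        folded = phase_fold(h, 10.0, 10.0)
        assert folded.shape == (10,)
        assert folded[2] == 1  # 325 mod 100 = 25 ms -> bin [20, 30)

    def test_constant_histogram_scales_by_cycles(self):
        folded = phase_fold(np.ones(100, dtype=int), 10.0, 10.0)
        assert np.all(folded == 10)

    def test_linearity(self, rng):
        a = rng.integers(0, 5, 100)
        b = rng.integers(0, 5, 100)
        assert np.array_equal(phase_fold(a + b, 10.0, 10.0),
                              phase_fold(a, 10.0, 10.0) + phase_fold(b, 10.0, 10.0))

    def test_non_integer_cycles_rejected(self):
        with pytest.raises(ValueError):
            phase_fold(np.ones(95), 10.0, 10.0)


class TestPhaseCorrelation:
    centers = (np.arange(100) + 0.5) * 1.0

    def test_sine_gives_plus_one(self):
        d = np.sin(2 * np.pi * 10 * self.centers * 1e-3)
        assert phase_correlation(d, 10.0) == pytest.approx(1.0)

    def test_antiphase_gives_minus_one(self):
        d = -np.sin(2 * np.pi * 10 * self.centers * 1e-3)
        assert phase_correlation(d, 10.0) == pytest.approx(-1.0)

    def test_quadrature_gives_zero(self):
        d = np.cos(2 * np.pi * 10 * self.centers * 1e-3)
        assert phase_correlation(d, 10.0) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_flagged_not_zero(self):
        assert np.isnan(phase_correlation(np.zeros(100), 10.0))

    def test_wrong_window_rejected(self):
        with pytest.raises(ValueError):
            phase_correlation(np.zeros(50), 10.0)


class TestHalfwaveStats:
    def test_uniform_spikes_center_on_quarter_periods(self):
        # dense uniform grid on one period: means at 25 and 75 ms exactly
        spikes = np.arange(0.5, 100.0, 1.0)
        hw = halfwave_stats([spikes], 10.0)
        assert hw.positive_mean_ms == pytest.approx(25.0)
        assert hw.negative_mean_ms == pytest.approx(75.0)
        assert hw.negative_mean_shifted_ms == pytest.approx(25.0)

    def test_all_spikes_in_positive_half(self):
        hw = halfwave_stats([np.full(7, 110.0)], 10.0)  # folds to 10 ms
        assert hw.positive_count == 7 and hw.negative_count == 0

    def test_counts_conserved(self, rng):
        spikes = rng.uniform(0, 1000.0, 137)
        hw = halfwave_stats([spikes], 10.0)
        assert hw.positive_count + hw.negative_count == 137

    def test_zero_frequency_rejected(self):
        with pytest.raises(ValueError):
            halfwave_stats([np.array([1.0])], 0.0)


class TestRateChange:
    def test_zero_for_identical_rates(self):
        assert relative_rate_change(7.0, 7.0) == 0.0

    def test_formula(self):
        assert relative_rate_change(11.0, 10.0) == pytest.approx(10.0)

    def test_undefined_baseline_flagged(self):
        assert np.isnan(relative_rate_change(1.0, 0.0))


class TestPipeline:
    def _surrogate(self, rng, eps, n_target=1000, f_t=10.0, duration=10000.0):
        """Inhomogeneous Poisson train, rate ~ (1 + eps sin(2 pi f_t t))."""
        lam = n_target / duration
        t = rng.uniform(0, duration, int(n_target * 2))
        keep = rng.uniform(0, 1 + abs(eps), t.size) \
            <= 1 + eps * np.sin(2 * np.pi * f_t * t * 1e-3)
        return np.sort(t[keep])

    def test_permutation_invariance(self, rng):
        trains = [rng.uniform(0, 1000.0, 30) for _ in range(6)]
        base = [rng.uniform(0, 1000.0, 30) for _ in range(6)]
        s1 = compute_phase_stats(trains, base, 10.0, 1000.0)
        s2 = compute_phase_stats(trains[::-1], base[::-1], 10.0, 1000.0)
        assert s1.correlation_r == pytest.approx(s2.correlation_r)
        assert np.array_equal(s1.folded_difference, s2.folded_difference)

    def test_modulation_sign_recovered(self):
        """Phase-locked surrogates: positive eps -> r > 0, every seed."""
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            mod = self._surrogate(rng, eps=0.5)
            base = self._surrogate(rng, eps=0.0, n_target=len(mod))
            s = compute_phase_stats([mod], [base], 10.0, 10000.0)
            hits += s.correlation_r > 0
        assert hits >= 49  # recovery probability > 0.99

    def test_null_modulation_gives_null_correlation(self):
        """eps = 0: |r| behaves like a null-sample Pearson coefficient."""
        rs = []
        for seed in range(100, 300):
            rng = np.random.default_rng(seed)
            a = self._surrogate(rng, eps=0.0)
            b = self._surrogate(rng, eps=0.0, n_target=len(a))
            s = compute_phase_stats([a], [b], 10.0, 10000.0)
            rs.append(s.correlation_r)
        rs = np.array(rs)
        # mean ~ 0 and spread consistent with a 100-bin sample correlation
        assert abs(np.mean(rs)) < 0.05
        frac_large = np.mean(np.abs(rs) > 1.96 / np.sqrt(100 - 2))
        assert frac_large < 0.25

    def test_rate_change_against_baseline(self, rng):
        trains = [rng.uniform(0, 1000.0, 12) for _ in range(4)]
        base = [rng.uniform(0, 1000.0, 10) for _ in range(4)]
        s = compute_phase_stats(trains, base, 10.0, 1000.0)
        assert s.rate_change_pct == pytest.approx(20.0)
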