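"""Trace analysis: filtering, autocovariance, fits, idealization, photons."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage, stats

import optogate as og
from optogate.trace import FluorescenceTrace


def brute_autocov(x, nlags):
    """Double-loop biased autocovariance oracle, normalized to C(0)=1."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xb = x - x.mean()
    c = np.empty(nlags + 1)
    for k in range(nlags + 1):
        s = 0.0
        for t in range(n - k):
            s += xb[t] * xb[t + k]
        c[k] = s / n
    return c / c[0]


class TestGaussianFilter:
    def test_constant_trace_preserved(self):
        tr = FluorescenceTrace(np.full(100, 3.7), dt=0.002)
        out = og.gaussian_filter(tr)
        assert np.allclose(out.values, 3.7)

    def test_impulse_response_is_normalized_symmetric_kernel(self):
        x = np.zeros(101)
        x[50] = 1.0
        out = og.gaussian_filter(FluorescenceTrace(x, dt=0.002)).values
        assert out.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(out, out[::-1], atol=1e-12)
        assert out[50] == out.max()

    def test_matches_direct_convolution_on_white_noise(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 4000)
        out = og.gaussian_filter(FluorescenceTrace(x, dt=0.002), 0.25).values
        impulse = np.zeros(41)
        impulse[20] = 1.0
        kernel = ndimage.gaussian_filter1d(impulse,
                                           np.sqrt(np.log(2)) / (2 * np.pi * 0.25))
        oracle = np.convolve(x, kernel, mode="same")
        assert np.allclose(out[25:-25], oracle[25:-25], atol=1e-10)
        # the kernel's power gain sets the variance reduction
        gain = (kernel ** 2).sum()
        assert out.var() == pytest.approx(gain * x.var(), rel=0.05)


class TestAutocovariance:
    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        # correlated trace: random walk increments smoothed
        x = np.cumsum(rng.normal(0, 1, 600))[:500]
        lags, c = og.autocovariance(FluorescenceTrace(x, dt=0.002), 0.05)
        oracle = brute_autocov(x, 25)
        assert np.allclose(c, oracle, atol=1e-10)

    def test_zero_lag_is_one(self):
        rng = np.random.default_rng(4)
        _, c = og.autocovariance(
            FluorescenceTrace(rng.normal(0, 1, 1000), dt=0.002), 0.02)
        assert c[0] == 1.0

    def test_iid_noise_decorrelates(self):
        rng = np.random.default_rng(5)
        n = 20_000
        _, c = og.autocovariance(
            FluorescenceTrace(rng.normal(0, 1, n), dt=0.002), 0.05)
        assert np.all(np.abs(c[1:]) < 3 / np.sqrt(n))

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError, match="fluctuations"):
            og.autocovariance(FluorescenceTrace(np.ones(100), dt=0.002), 0.01)


class TestExpDecayFit:
    def test_single_component_noiseless_recovery(self):
        lags = np.arange(0, 0.1, 0.002)
        c = np.exp(-lags / 0.010)
        fit = og.fit_exp_decay(lags, c, n_components=1)
        assert fit.taus[0] == pytest.approx(0.010, rel=1e-6)

    def test_two_component_noiseless_recovery(self):
        lags = np.arange(0, 1.0, 0.002)
        c = 0.5 * np.exp(-lags / 0.013) + 0.5 * np.exp(-lags / 0.148)
        fit = og.fit_exp_decay(lags, c, n_components=2)
        assert fit.taus[0] == pytest.approx(0.013, rel=1e-3)
        assert fit.taus[1] == pytest.approx(0.148, rel=1e-3)
        assert np.allclose(fit.amplitudes, 0.5, rtol=1e-2)

    def test_invalid_component_count_rejected(self):
        lags = np.arange(0, 0.1, 0.002)
        with pytest.raises(ValueError):
            og.fit_exp_decay(lags, np.exp(-lags / 0.01), n_components=3)

    def test_model_selection_prefers_one_component_for_single_tau(self):
        # single-relaxation background: the residual-ratio rule should not
        # invent a second component in (almost) any realization
        prefer_one = 0
        for seed in range(20):
            path = og.simulate_telegraph(58.8, 58.8, 50.0, seed=seed)
            tr = FluorescenceTrace(path.bin_average(0.002), dt=0.002)
            lags, c = og.autocovariance(tr, 0.1)
            n, _ = og.select_components(lags, c)
            prefer_one += (n == 1)
        assert prefer_one >= 19

    def test_model_selection_finds_two_for_separated_taus(self):
        lags = np.arange(0, 1.0, 0.002)
        c = 0.5 * np.exp(-lags / 0.013) + 0.5 * np.exp(-lags / 0.148)
        n, ratio = og.select_components(lags, c)
        assert n == 2 and ratio < 0.01


class TestIdealize:
    def test_constant_background_is_all_L0(self):
        tr = FluorescenceTrace(np.zeros(50), dt=0.002)
        ideal = og.idealize(tr, 0.0, 1.0, 2.5)
        assert ideal.p_l1 == 0.0
        assert ideal.dwells_L1.size == 0
        assert ideal.dwells_L0.tolist() == [50 * 0.002]

    def test_hand_built_trace_dwells(self):
        tr = FluorescenceTrace(
            np.array([0, 0, 5, 5, 5, 0, 5, 0, 0, 0], dtype=float), dt=0.002)
        ideal = og.idealize(tr, 0.0, 1.0, 2.5)
        assert ideal.threshold == 2.5
        assert sorted(ideal.dwells_L1.tolist()) == [0.002, 0.006]
        assert ideal.p_l1 == pytest.approx(0.4)
        assert ideal.n_up_transitions == 2
        # total dwell time covers the trace
        assert ideal.dwells_L0.sum() + ideal.dwells_L1.sum() == pytest.approx(
            tr.duration)

    def test_pure_background_false_positive_rate(self):
        rng = np.random.default_rng(8)
        tr = FluorescenceTrace(rng.normal(0, 1, 100_000), dt=0.002)
        ideal = og.idealize(tr, 0.0, 1.0, 2.5)
        expected = 1 - stats.norm.cdf(2.5)  # one-sided tail, ~0.62%
        assert ideal.p_l1 == pytest.approx(expected, abs=0.002)
        assert ideal.p_l1 < 0.02

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=1), min_size=2, max_size=200))
    def test_dwell_reconstruction_is_lossless(self, bits):
        values = np.array(bits, dtype=float) * 10.0
        ideal = og.idealize(FluorescenceTrace(values, dt=0.002), 0.0, 1.0, 2.5)
        levels, lengths = ideal.runs()
        rebuilt = np.repeat(levels, lengths)
        assert np.array_equal(rebuilt, ideal.levels)

    def test_filtered_square_wave_dwells_shift_at_most_kernel_halfwidth(self):
        period = 100  # samples; amplitude 10 sigma
        x = np.tile(np.concatenate([np.zeros(period), np.full(period, 10.0)]), 10)
        tr = FluorescenceTrace(x, dt=0.002)
        ideal_raw = og.idealize(tr, 0.0, 1.0, 2.5)
        ideal_filt = og.idealize(og.gaussian_filter(tr), 0.0, 1.0, 2.5)
        raw = np.sort(ideal_raw.dwells_L1)
        filt = np.sort(ideal_filt.dwells_L1)
        assert raw.size == filt.size
        assert np.max(np.abs(raw - filt)) <= 2 * tr.dt


class TestDwellStatistics:
    def test_exact_alternation(self):
        x = np.tile(np.concatenate([np.zeros(50), np.full(50, 10.0)]), 8)
        ideal = og.idealize(FluorescenceTrace(x, dt=0.002), 0.0, 1.0, 2.5)
        ds = og.dwell_statistics(ideal)
        assert ds.mean_L1 == pytest.approx(0.1)
        assert ds.sem_L1 == pytest.approx(0.0, abs=1e-12)

    def test_no_transitions_is_an_error(self):
        ideal = og.idealize(FluorescenceTrace(np.zeros(100), dt=0.002), 0.0, 1.0)
        with pytest.raises(ValueError):
            og.dwell_statistics(ideal)

    def test_exponential_dwells_unbiased_within_sem(self):
        # telegraph ground truth: mean L1 dwell = 1/k10
        errors = []
        for seed in range(8):
            path = og.simulate_telegraph(5.0, 10.0, 400.0, seed=seed)
            tr = FluorescenceTrace(10.0 * path.bin_average(0.002), dt=0.002)
            ideal = og.idealize(tr, 0.0, 1e-6, 2.5)
            ds = og.dwell_statistics(ideal)
            errors.append((ds.mean_L1 - 0.1) / ds.sem_L1)
        # standardized errors should look like N(0, 1): mean within 3/sqrt(n)
        assert abs(np.mean(errors)) < 3 / np.sqrt(len(errors)) + 1.0


class TestBleachSteps:
    @pytest.mark.parametrize("n_steps,levels", [
        (1, [10.0, 0.0]),
        (3, [30.0, 20.0, 10.0, 0.0]),
    ])
    def test_noiseless_steps_counted_exactly(self, n_steps, levels):
        x = np.concatenate([np.full(150, v) for v in levels])
        res = og.count_bleach_steps(FluorescenceTrace(x, dt=0.002), min_step=5.0)
        assert res.n_steps == n_steps
        assert res.is_single_emitter == (n_steps == 1)

    def test_flat_noise_has_no_steps(self):
        rng = np.random.default_rng(1)
        tr = FluorescenceTrace(rng.normal(0, 1, 3000), dt=0.002)
        assert og.count_bleach_steps(tr, min_step=1.0).n_steps == 0

    def test_synthetic_three_fluorophore_traces(self):
        m = og.EmitterModel(k_open_max=0.0, k_close=0.0, k_blink_off=0.0,
                            k_blink_on=0.0, k_bleach=0.1, brightness=5.0,
                            bg_mean=0.0, bg_sd=1.0, n_fluors=3)
        hits = 0
        for seed in range(20):
            tr = og.simulate_emitter_trace(m, 0.0, 60.0, 0.002, seed=seed)
            hits += og.count_bleach_steps(tr, min_step=2.5).n_steps == 3
        assert hits >= 18


class TestRoisAndPhotonCounts:
    def test_single_bright_pixel_single_roi(self):
        stack = np.zeros((5, 8, 8))
        stack[:, 3, 4] = 10.0
        rois = og.define_rois(stack)
        assert len(rois) == 1 and rois[0].tolist() == [[3, 4]]

    def test_two_disjoint_blocks_two_rois(self):
        stack = np.zeros((2, 16, 16))
        stack[:, 1:3, 1:3] = 5.0
        stack[:, 10:12, 10:12] = 5.0
        rois = og.define_rois(stack, threshold_quantile=0.9)
        assert len(rois) == 2

    def test_recovers_generated_spot_pixels(self):
        spot = [(r, c) for r in range(10, 13) for c in range(30, 33)]
        stack = og.simulate_photon_frames(1.0, 20.0, spot, n_frames=500, seed=6)
        # quantile chosen so the foreground area matches the spot area
        rois = og.define_rois(stack, threshold_quantile=1 - len(spot) / 2048)
        assert len(rois) == 1
        assert sorted(map(tuple, rois[0].tolist())) == sorted(spot)

    def test_poisson_mode(self):
        stack = og.simulate_photon_frames(4.0, 0.0, [], shape=(16, 16),
                                          n_frames=3000, seed=7)
        summary = og.photon_count_analysis(stack, rois=[])
        # Poisson(4): counts 3 and 4 share the maximal pmf
        assert summary.modes["background"] in (3, 4)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            og.photon_count_analysis(np.empty((0, 4, 4)), rois=[])

    def test_spot_mode_not_below_background_mode(self):
        spot = [(2, 2), (2, 3)]
        stack = og.simulate_photon_frames(2.0, 6.0, spot, shape=(8, 8),
                                          n_frames=4000, seed=8)
        summary = og.photon_count_analysis(stack, rois=[np.array(spot)])
        assert min(summary.modes["spot"]) >= summary.modes["background"]


class TestCompareModes:
    def test_identical_groups_maximal_p(self):
        u, p = og.compare_modes([5, 5, 5, 5], [5, 5, 5, 5])
        assert p == pytest.approx(1.0)

    def test_disjoint_groups_minimal_p(self):
        u, p = og.compare_modes([1, 2, 3, 4], [10, 11, 12, 13])
        assert u == 0.0
        assert p == pytest.approx(2 / 70, rel=1e-6)  # exact two-sided, n=4

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            og.compare_modes([1, 2], [3, 4, 5])

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(9)
        false_pos = 0
        reps = 400
        for _ in range(reps):
            a = rng.normal(0, 1, 4)
            b = rng.normal(0, 1, 4)
            _, p = og.compare_modes(a, b)
            false_pos += p < 0.05
        # exact n=4 test: attainable level below 0.05 is 2/70 ~ 2.9%
        assert false_pos / reps < 0.08


class TestEnsembleAverage:
    def test_identical_traces(self):
        tr = FluorescenceTrace(np.arange(10, dtype=float), dt=0.002)
        mean, sd = og.ensemble_average([tr, tr, tr])
        assert np.array_equal(mean.values, tr.values)
        assert np.all(sd == 0.0)

    def test_symmetric_pair_population_sd(self):
        a = FluorescenceTrace(np.full(20, 2.0), dt=0.002)
        b = FluorescenceTrace(np.full(20, -2.0), dt=0.002)
        mean, sd = og.ensemble_average([a, b])
        assert np.allclose(mean.values, 0.0)
        assert np.allclose(sd, 2.0)

    def test_mismatched_lengths_rejected(self):
        a = FluorescenceTrace(np.zeros(10), dt=0.002)
        b = FluorescenceTrace(np.zeros(12), dt=0.002)
        with pytest.raises(ValueError):
            og.ensemble_average([a, b])

    def test_agonist_onset_raises_mean_and_sd(self, quiet_emitter):
        # spots recorded before (no agonist -> dark) and after saturating dose
        before, after = [], []
        for seed in range(12):
            off = og.simulate_emitter_trace(quiet_emitter, 0.0, 10.0, 0.002,
                                            seed=seed)
            on = og.simulate_emitter_trace(quiet_emitter, 3.0, 10.0, 0.002,
                                           seed=100 + seed)
            before.append(off)
            after.append(on)
        m0, s0 = og.ensemble_average(before)
        m1, s1 = og.ensemble_average(after)
        assert m1.values.mean() > m0.values.mean() + 1.0
        assert s1.mean() > s0.mean() + 1.0


def test_background_tail_mass_two_sided_constant():
    assert og.background_tail_mass(2.5) == pytest.approx(0.98758, abs=1e-5)
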