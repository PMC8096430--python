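"""Spectral factorization, conditional Granger causality, DAI."""

import numpy as np
import pytest

from stopbeta.connectivity import (_conditional_gc, compute_dai,
                                   conditional_gc_spectrum, dai_ssrt_correlation,
                                   dai_table, gc_bias_threshold,
                                   group_contrast, wilson_factorize)
from stopbeta.spectral import _tapered_fft

FS = 400.0


def simulate_var2(coupling=(0.25, 0.0), n_trials=500, n_samples=400,
                  r=0.9, f0=32.0, seed=0, common_driver=False):
    """Stable AR(2) oscillator pair (plus optional driver) for oracles."""
    rng = np.random.default_rng(seed)
    a1 = 2 * r * np.cos(2 * np.pi * f0 / FS)
    a2 = -r ** 2
    nch = 3 if common_driver else 2
    x = np.zeros((n_trials, nch, n_samples + 200))
    e = rng.standard_normal((n_trials, nch, n_samples + 200))
    c_fwd, c_bwd = coupling
    for t in range(2, n_samples + 200):
        if common_driver:
            x[:, 2, t] = a1 * x[:, 2, t - 1] + a2 * x[:, 2, t - 2] + e[:, 2, t]
            drive_x = 0.35 * x[:, 2, t - 1]
            drive_y = 0.35 * x[:, 2, t - 2]
        else:
            drive_x = drive_y = 0.0
        x[:, 0, t] = (a1 * x[:, 0, t - 1] + a2 * x[:, 0, t - 2]
                      + c_bwd * x[:, 1, t - 1] + drive_x + e[:, 0, t])
        x[:, 1, t] = (a1 * x[:, 1, t - 1] + a2 * x[:, 1, t - 2]
                      + c_fwd * x[:, 0, t - 1] + drive_y + e[:, 1, t])
    return x[:, :, 200:]


def csd_of(x, half_bandwidth=2.0, nfft=512):
    spec, freqs, k = _tapered_fft(x - x.mean(-1, keepdims=True), FS,
                                  half_bandwidth, nfft)
    csd = np.einsum("rkcf,rkdf->fcd", spec, spec.conj()) / (x.shape[0] * k)
    return csd, freqs


def analytic_pairwise_gc(coupling, freqs, r=0.9, f0=32.0):
    """Closed-form Geweke GC x->y from the true VAR coefficients."""
    a1 = 2 * r * np.cos(2 * np.pi * f0 / FS)
    a2 = -r ** 2
    A1 = np.array([[a1, coupling[1]], [coupling[0], a1]])
    A2 = np.diag([a2, a2])
    out = np.empty(freqs.size)
    for i, f in enumerate(freqs):
        z = np.exp(-2j * np.pi * f / FS)
        H = np.linalg.inv(np.eye(2) - A1 * z - A2 * z ** 2)
        S_yy = np.real((H @ H.conj().T)[1, 1])
        out[i] = np.log(S_yy / np.abs(H[1, 1]) ** 2)
    return out


class TestWilsonFactorize:
    def test_diagonal_white_noise_closed_form(self):
        nf = 33
        S = np.broadcast_to(np.diag([2.0, 3.0]).astype(complex),
                            (nf, 2, 2)).copy()
        res = wilson_factorize(S, np.linspace(0, 200, nf))
        assert np.abs(res.transfer - np.eye(2)).max() < 1e-10
        assert np.allclose(np.diag(res.noise_cov), [2.0, 3.0])

    def test_var_innovation_covariance_recovered(self):
        # long stationary segments keep the windowing bias below 5%
        x = simulate_var2(seed=1, n_trials=600, n_samples=800)
        csd, freqs = csd_of(x, half_bandwidth=1.5, nfft=1024)
        res = wilson_factorize(csd, freqs)
        # unit innovations, one-sided PSD scaling 2/fs
        sigma = res.noise_cov * FS / 2.0
        assert np.abs(np.diag(sigma) - 1.0).max() < 0.05
        assert abs(sigma[0, 1]) < 0.05

    def test_reconstruction_within_tolerance(self):
        x = simulate_var2(seed=2, n_trials=100)
        csd, freqs = csd_of(x)
        res = wilson_factorize(csd, freqs)
        rec = res.transfer @ res.noise_cov @ \
            res.transfer.conj().transpose(0, 2, 1)
        rel = np.linalg.norm(rec - csd) / np.linalg.norm(csd)
        assert rel < 1e-3
        assert res.residual < 1e-3

    def test_noise_cov_symmetric_positive_definite(self):
        x = simulate_var2(seed=3, n_trials=100)
        csd, freqs = csd_of(x)
        res = wilson_factorize(csd, freqs)
        assert np.allclose(res.noise_cov, res.noise_cov.T)
        assert np.all(np.linalg.eigvalsh(res.noise_cov) > 0)


class TestConditionalGC:
    def test_coupled_var_peaks_in_band_reverse_at_bias(self):
        x = simulate_var2(coupling=(0.25, 0.0), n_trials=600, seed=4)
        csd, freqs = csd_of(x)
        fwd = _conditional_gc(csd, freqs, tgt=[1], src=[0], cond=[])
        rev = _conditional_gc(csd, freqs, tgt=[0], src=[1], cond=[])
        band = (freqs >= 20) & (freqs <= 45)
        assert freqs[np.argmax(fwd)] == pytest.approx(32.0, abs=6.0)
        assert fwd[band].mean() > 10 * abs(rev[band].mean())

    def test_matches_analytic_geweke_at_peak(self):
        # long stationary segments, 1000 trials, narrow smoothing
        x = simulate_var2(coupling=(0.25, 0.0), n_trials=1000,
                          n_samples=400, seed=5)
        csd, freqs = csd_of(x, half_bandwidth=1.0)
        est = _conditional_gc(csd, freqs, tgt=[1], src=[0], cond=[])
        oracle = analytic_pairwise_gc((0.25, 0.0), freqs)
        pk = np.argmax(oracle)
        assert abs(est[pk] - oracle[pk]) / oracle[pk] < 0.10

    def test_common_driver_explained_away_by_conditioning(self):
        x = simulate_var2(coupling=(0.0, 0.0), n_trials=600, seed=6,
                          common_driver=True)
        csd, freqs = csd_of(x)
        band = (freqs >= 20) & (freqs <= 45)
        pair = _conditional_gc(csd, freqs, tgt=[1], src=[0], cond=[])
        cond = _conditional_gc(csd, freqs, tgt=[1], src=[0], cond=[2])
        assert pair[band].mean() > 5 * cond[band].mean()
        assert cond[band].mean() < 0.05

    def test_independent_sources_near_zero_both_ways(self):
        x = simulate_var2(coupling=(0.0, 0.0), n_trials=500, seed=7)
        csd, freqs = csd_of(x)
        band = (freqs >= 8) & (freqs <= 44)
        for tgt, src in (([1], [0]), ([0], [1])):
            gc = _conditional_gc(csd, freqs, tgt=tgt, src=src, cond=[])
            assert abs(gc[band].mean()) < 0.02

    def test_numerically_nonnegative(self):
        x = simulate_var2(coupling=(0.2, 0.1), n_trials=300, seed=8)
        csd, freqs = csd_of(x)
        gc = _conditional_gc(csd, freqs, tgt=[1], src=[0], cond=[])
        assert gc.min() > -1e-6


class TestComputeDAI:
    def test_symmetry_bounds_and_arithmetic(self):
        assert compute_dai(0.4, 0.4) == 0.0
        assert compute_dai(0.4, 0.0) == 1.0
        assert compute_dai(0.3, 0.1) == pytest.approx(0.5)

    def test_antisymmetric_exactly(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a, b = rng.uniform(0, 1, 2)
            assert compute_dai(a, b) == -compute_dai(b, a)

    def test_both_zero_undefined(self):
        assert np.isnan(compute_dai(0.0, 0.0))

    def test_dai_in_unit_interval(self):
        rng = np.random.default_rng(10)
        vals = [compute_dai(a, b) for a, b in rng.uniform(0, 5, (50, 2))]
        assert np.all(np.abs(vals) <= 1.0)


class TestDaiSsrtCorrelation:
    def test_six_frequencies_and_ci_level(self):
        rng = np.random.default_rng(11)
        freqs = np.arange(30.0, 41.0, 2.0)
        assert freqs.size == 6
        dai = rng.uniform(-1, 1, (30, 6))
        ssrt = rng.normal(240, 30, 30)
        out = dai_ssrt_correlation(dai, ssrt, freqs=freqs, n_boot=200, seed=0)
        assert len(out) == 6
        assert out[0]["ci_level"] == pytest.approx(99.1666, abs=1e-3)

    def test_injected_negative_slope_detected(self):
        rng = np.random.default_rng(12)
        n = 55
        dai = rng.uniform(-1, 1, n)
        ssrt = 240 - 25 * dai + 10 * rng.standard_normal(n)
        out = dai_ssrt_correlation(dai[:, None], ssrt, n_boot=500, seed=1)
        assert out[0]["r"] < -0.3
        assert out[0]["significant"]

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            dai_ssrt_correlation(np.zeros((12, 1)), np.ones(12))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            dai_ssrt_correlation(np.random.rand(5, 1),
                                 np.random.rand(5))


class TestEpochLevelGC:
    @pytest.fixture(scope="class")
    def coupled_epochs(self):
        from stopbeta.synthetic import (NeuralConfig, SimConfig, VarCoupling,
                                        simulate_behavior,
                                        simulate_source_epochs)
        cfg = SimConfig(n_subjects=1, trials_per_subject=900, seed=31)
        trials = simulate_behavior(cfg)
        ncfg = NeuralConfig(seed=31, sources=("rIFG", "pre-SMA", "lMFG"),
                            var_coupling=VarCoupling(coupling=(0.3, 0.0)))
        return simulate_source_epochs(trials, ncfg)

    def test_condition_gated_coupling(self, coupled_epochs):
        gs = conditional_gc_spectrum(coupled_epochs, ("rIFG", "pre-SMA"),
                                     condition="sSTOP")
        ga = conditional_gc_spectrum(coupled_epochs, ("rIFG", "pre-SMA"),
                                     condition="cAC-GO")
        assert gs.band_mean() > 5 * max(ga.band_mean(), 1e-6)

    def test_bias_threshold_significance(self, coupled_epochs):
        sig = gc_bias_threshold(coupled_epochs, ("rIFG", "pre-SMA"),
                                condition="sSTOP", n_perm=60, seed=0)
        null = gc_bias_threshold(coupled_epochs, ("pre-SMA", "rIFG"),
                                 condition="cAC-GO", n_perm=60, seed=1)
        assert sig.significant
        assert not null.significant

    def test_zero_permutations_rejected(self, coupled_epochs):
        with pytest.raises(ValueError):
            gc_bias_threshold(coupled_epochs, ("rIFG", "pre-SMA"),
                              condition="sSTOP", n_perm=0)

    def test_too_few_trials_rejected(self, coupled_epochs):
        small = coupled_epochs.select(np.arange(30))
        with pytest.raises(ValueError, match="trials"):
            gc_bias_threshold(small, ("rIFG", "pre-SMA"),
                              condition="sSTOP", n_perm=10)


class TestGroupContrast:
    @staticmethod
    def fake_spectra(n_sub, effect, seed):
        from stopbeta.connectivity import GCSpectrum
        rng = np.random.default_rng(seed)
        freqs = np.linspace(0, 200, 129)
        band = (freqs >= 25) & (freqs <= 40)
        gs, ga = [], []
        for s in range(n_sub):
            base = np.abs(0.02 * rng.standard_normal(freqs.size))
            bump = effect * band * rng.uniform(0.7, 1.3)
            gs.append(GCSpectrum(s, ("a", "b"), "sSTOP", freqs,
                                 base + bump, significant=True))
            ga.append(GCSpectrum(s, ("a", "b"), "cAC-GO", freqs,
                                 np.abs(0.02 * rng.standard_normal(
                                     freqs.size)), significant=False))
        return gs, ga

    def test_gated_effect_yields_cluster(self):
        gs, ga = self.fake_spectra(14, 0.2, seed=13)
        res = group_contrast(gs, ga, n_perm=1000, seed=0)
        assert len(res.significant) >= 1
        sig_freqs = res.freqs[res.significance_mask]
        assert sig_freqs.min() >= 20 and sig_freqs.max() <= 45

    def test_identical_conditions_no_cluster(self):
        gs, _ = self.fake_spectra(10, 0.0, seed=14)
        res = group_contrast(gs, gs, n_perm=500, seed=1)
        assert res.significant == []

    def test_bonferroni_correction_reported(self):
        gs, ga = self.fake_spectra(12, 0.2, seed=15)
        res = group_contrast(gs, ga, n_perm=500, seed=2, n_links=2)
        c = res.clusters[0]
        assert c.p_corrected == pytest.approx(min(1.0, 2 * c.p_value))


def test_dai_table_interpolates_spectra():
    from stopbeta.connectivity import GCSpectrum
    freqs = np.linspace(0, 100, 51)
    ab = GCSpectrum(0, ("a", "b"), "s", freqs, np.full(51, 0.3))
    ba = GCSpectrum(0, ("b", "a"), "s", freqs, np.full(51, 0.1))
    dai = dai_table(ab, ba, [30.0, 34.0, 41.0])
    assert np.allclose(dai, 0.5)


def test_sliding_window_contrast_is_time_specific():
    """Coupling gated to the tROI shows up only in overlapping windows;
    windows outside the epoch span are skipped."""
    from stopbeta.connectivity import sliding_window_contrast
    from stopbeta.synthetic import (NeuralConfig, SimConfig, VarCoupling,
                                    simulate_behavior, simulate_source_epochs)
    rng = np.random.default_rng(99)
    cohort = []
    for s in range(10):
        trials = simulate_behavior(SimConfig(
            n_subjects=1, trials_per_subject=700, seed=400 + s))
        ep = simulate_source_epochs(trials, NeuralConfig(
            seed=400 + s, sources=("rIFG", "pre-SMA"),
            var_coupling=VarCoupling(coupling=(0.3, 0.0),
                                     gate_window=(100.0, 350.0))))
        # equalize condition trial counts: GC estimation bias scales with
        # 1/n_trials, so unequal counts alone would shift the contrast
        lab = ep.trials["outcome"].to_numpy()
        i_s = np.flatnonzero(lab == "sSTOP")
        i_a = rng.permutation(np.flatnonzero(lab == "cAC-GO"))[:i_s.size]
        cohort.append(ep.select(np.sort(np.concatenate([i_s, i_a]))))
    # the pre-gate window is the clean null: coupling is causal, so unlike
    # post-gate windows it cannot inherit cross-covariance from the
    # oscillators' memory
    windows = ((-150.0, 100.0), (100.0, 350.0), (2000.0, 2250.0))
    res = sliding_window_contrast(cohort, ("rIFG", "pre-SMA"),
                                  conditioning=[], windows=windows,
                                  n_perm=2000, seed=0, n_links=1)
    assert res[(2000.0, 2250.0)] is None          # outside the epoch span
    in_gate = res[(100.0, 350.0)]
    pre_gate = res[(-150.0, 100.0)]
    p_in = min((c.p_value for c in in_gate.clusters if c.mass > 0),
               default=1.0)
    p_pre = min((c.p_value for c in pre_gate.clusters if c.mass > 0),
                default=1.0)
    assert p_in <= in_gate.alpha                   # detected in the gate
    assert p_pre > pre_gate.alpha                  # absent before it
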