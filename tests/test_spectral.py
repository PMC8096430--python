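"""Spectral estimation: windows, tapers, CSD, TFR, z-scoring, PCA, bands."""

import numpy as np
import pytest
from scipy import signal as sps

from conftest import make_epochs
from stopbeta.spectral import (AnalysisParams, baseline_z_transform,
                               compute_tfr, cycle_align_window,
                               identify_bands, multitaper_csd, n_tapers,
                               principal_component_reduce)


class TestCycleAlignWindow:
    def test_beta_band_worked_example(self):
        # 100-350 ms extended to six full 22 Hz cycles ends at 373 ms
        assert cycle_align_window((100.0, 350.0), 22.0) == (100.0, 373.0)

    def test_exact_integer_cycles_unchanged(self):
        assert cycle_align_window((0.0, 100.0), 10.0) == (0.0, 100.0)
        assert cycle_align_window((0.0, 500.0), 20.0) == (0.0, 500.0)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            cycle_align_window((0.0, 100.0), 0.0)


class TestTaperCounts:
    def test_beta_and_gamma_counts(self):
        # T = 273 ms: four tapers at +-10 Hz, five at +-12 Hz smoothing
        assert n_tapers(0.273, 10.0) == 4
        assert n_tapers(0.273, 12.0) == 5

    def test_too_small_bandwidth_rejected(self):
        with pytest.raises(ValueError, match="taper"):
            n_tapers(0.05, 5.0)


class TestMultitaperCSD:
    def test_white_noise_coherence_near_zero(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((500, 2, 1, 600))
        ep = make_epochs(data, delays=200.0)
        csd = multitaper_csd(ep, (0.0, 600.0), 22.0, 5.0)
        S = csd.matrices
        band = (csd.freq_grid > 5) & (csd.freq_grid < 150)
        coh = np.abs(S[band, 0, 1]) / np.sqrt(
            np.real(S[band, 0, 0]) * np.real(S[band, 1, 1]))
        assert np.max(coh) < 0.1

    def test_hermitian_and_nonnegative_diagonal(self):
        rng = np.random.default_rng(1)
        ep = make_epochs(rng.standard_normal((20, 2, 1, 600)))
        csd = multitaper_csd(ep, (0.0, 500.0), 22.0, 6.0)
        assert np.all(np.real(np.diagonal(csd.matrices, axis1=1, axis2=2))
                      >= 0)

    def test_var_csd_matches_analytic_spectrum(self):
        # CSD of a known stable VAR(2) vs its closed-form H(f) Sigma H*(f)
        fs = 400.0
        r, f0, c = 0.85, 24.0, 0.2
        a1 = 2 * r * np.cos(2 * np.pi * f0 / fs)
        a2 = -r ** 2
        rng = np.random.default_rng(2)
        nt, ns = 1000, 512
        x = np.zeros((nt, 2, ns + 200))
        e = rng.standard_normal((nt, 2, ns + 200))
        for t in range(2, ns + 200):
            x[:, 0, t] = a1 * x[:, 0, t - 1] + a2 * x[:, 0, t - 2] + e[:, 0, t]
            x[:, 1, t] = (a1 * x[:, 1, t - 1] + a2 * x[:, 1, t - 2]
                          + c * x[:, 0, t - 1] + e[:, 1, t])
        ep = make_epochs(x[:, :, None, 200:], delays=0.0, t0=0.0)
        csd = multitaper_csd(ep, (0.0, 1275.0), 22.0, 2.0, nfft=512)

        A1 = np.array([[a1, 0.0], [c, a1]])
        A2 = np.diag([a2, a2])
        band = (csd.freq_grid >= 15) & (csd.freq_grid <= 35)
        rel = []
        for fi in np.flatnonzero(band):
            f = csd.freq_grid[fi]
            z = np.exp(-2j * np.pi * f / fs)
            H = np.linalg.inv(np.eye(2) - A1 * z - A2 * z ** 2)
            S_true = (H @ H.conj().T) * 2.0 / fs  # one-sided PSD scaling
            rel.append(np.linalg.norm(csd.matrices[fi] - S_true)
                       / np.linalg.norm(S_true))
        assert np.mean(rel) < 0.05

    def test_band_power_tracks_time_domain_variance(self):
        # Parseval-type check on band-limited signals
        rng = np.random.default_rng(3)
        sos = sps.butter(4, [12, 32], "bandpass", fs=400.0, output="sos")
        x = sps.sosfiltfilt(sos, rng.standard_normal((50, 1, 1, 512)), axis=-1)
        ep = make_epochs(x, t0=0.0, delays=0.0)
        csd = multitaper_csd(ep, (0.0, 1275.0), 22.0, 4.0, nfft=512)
        df = csd.freq_grid[1] - csd.freq_grid[0]
        integrated = np.real(csd.matrices[:, 0, 0]).sum() * df
        assert abs(integrated - x.var()) / x.var() < 0.10


class TestComputeTFR:
    def test_pure_sinusoid_peaks_at_its_frequency(self):
        fs = 400.0
        times = np.arange(-600, 1001, 1000.0 / fs)
        x = np.sin(2 * np.pi * 20.0 * times / 1000.0)
        data = np.tile(x, (4, 1, 1, 1))
        ep = make_epochs(data, delays=200.0)
        tfr = compute_tfr(ep, AnalysisParams(), "s0")
        avg = np.nanmean(tfr.average(), axis=1)
        assert tfr.freq_grid[np.nanargmax(avg)] == pytest.approx(20.0)

    def test_zero_signal_zero_power(self):
        data = np.zeros((3, 1, 1, 641))
        ep = make_epochs(data, delays=200.0)
        tfr = compute_tfr(ep, AnalysisParams(), "s0")
        assert np.nanmax(tfr.power) == 0.0

    def test_amplitude_step_tracked_within_window_length(self):
        # power time course follows an envelope step within one Hanning
        # window (3 cycles) of the step time
        fs = 400.0
        times = np.arange(-600, 1001, 1000.0 / fs)
        f = 20.0
        step_t = 400.0  # 200 ms after the 200 ms signal delay
        amp = np.where(times >= step_t, 2.0, 1.0)
        x = amp * np.sin(2 * np.pi * f * times / 1000.0)
        ep = make_epochs(np.tile(x, (2, 1, 1, 1)), delays=200.0)
        tfr = compute_tfr(ep, AnalysisParams(), "s0")
        fi = np.argmin(np.abs(tfr.freq_grid - f))
        series = np.nanmean(tfr.power[:, fi, :], axis=0)
        t = tfr.time_grid  # signal-locked; step at 200 ms post-signal
        win_ms = 3.0 / f * 1000.0
        before = series[t < 200.0 - win_ms].mean()
        after = series[(t > 200.0 + win_ms) & (t < 600.0)].mean()
        assert after / before == pytest.approx(4.0, rel=0.15)
        mid = series[np.argmin(np.abs(t - 200.0))]
        assert before < mid < after


class TestBaselineZTransform:
    @staticmethod
    def toy_tfrs():
        rng = np.random.default_rng(4)
        fs = 400.0
        data_a = rng.standard_normal((8, 1, 1, 801))
        data_b = rng.standard_normal((8, 1, 1, 801))
        ep_a = make_epochs(data_a, delays=200.0)
        ep_b = make_epochs(data_b, delays=200.0, outcome="cAC-GO",
                           rts=600.0)
        p = AnalysisParams()
        return compute_tfr(ep_a, p, "s0"), compute_tfr(ep_b, p, "s0")

    def test_identical_conditions_cancel(self):
        tfr_a, _ = self.toy_tfrs()
        za, zb = baseline_z_transform(tfr_a, tfr_a)
        assert np.nanmax(np.abs(za.power - zb.power)) == 0.0

    def test_hand_computed_two_trial_toy(self):
        tfr_a, tfr_b = self.toy_tfrs()
        za, zb = baseline_z_transform(tfr_a, tfr_b)
        pooled = np.concatenate([tfr_a.baseline_power, tfr_b.baseline_power])
        sd = pooled.std(axis=0, ddof=1)
        mean_a = tfr_a.baseline_power.mean(axis=0)
        manual = (tfr_a.power - mean_a[None, :, None]) / sd[None, :, None]
        assert np.allclose(za.power, manual, equal_nan=True)

    def test_common_rescaling_invariance(self):
        from dataclasses import replace
        tfr_a, tfr_b = self.toy_tfrs()
        za, zb = baseline_z_transform(tfr_a, tfr_b)
        sa = replace(tfr_a, power=tfr_a.power * 7.0,
                     baseline_power=tfr_a.baseline_power * 7.0)
        sb = replace(tfr_b, power=tfr_b.power * 7.0,
                     baseline_power=tfr_b.baseline_power * 7.0)
        za2, _ = baseline_z_transform(sa, sb)
        assert np.allclose(za.power, za2.power, equal_nan=True)

    def test_zero_pooled_sd_rejected(self):
        from dataclasses import replace
        tfr_a, tfr_b = self.toy_tfrs()
        flat_a = replace(tfr_a, baseline_power=np.ones_like(
            tfr_a.baseline_power))
        flat_b = replace(tfr_b, baseline_power=np.ones_like(
            tfr_b.baseline_power))
        with pytest.raises(ValueError, match="SD"):
            baseline_z_transform(flat_a, flat_b)


class TestPrincipalComponentReduce:
    def test_recovers_dominant_mixing_direction(self):
        rng = np.random.default_rng(5)
        src = rng.standard_normal((30, 1, 1, 400))
        mix = np.array([1.0, 0.3, 0.1])
        data = mix[None, None, :, None] * src \
            + 0.05 * rng.standard_normal((30, 1, 3, 400))
        ep = make_epochs(data)
        red = principal_component_reduce(ep, 1)
        r = np.corrcoef(red.data[:, 0, 0].ravel(), src[:, 0, 0].ravel())[0, 1]
        assert abs(r) > 0.95

    def test_full_rank_projection_conserves_variance(self):
        rng = np.random.default_rng(6)
        data = rng.standard_normal((10, 2, 3, 300))
        ep = make_epochs(data)
        red = principal_component_reduce(ep, 3)
        for si in range(2):
            v0 = ep.data[:, si].var(axis=(0, 2)).sum()
            v1 = red.data[:, si].var(axis=(0, 2)).sum()
            assert v1 == pytest.approx(v0, rel=1e-6)

    def test_duplicated_component_concentrates_variance(self):
        rng = np.random.default_rng(7)
        base = rng.standard_normal((10, 1, 1, 300))
        data = np.concatenate([base, base, np.zeros_like(base)], axis=2)
        ep = make_epochs(data)
        red = principal_component_reduce(ep, 1)
        assert red.data[:, 0, 0].var() == pytest.approx(
            2 * base.var(), rel=1e-6)

    def test_rank_deficient_rejected(self):
        base = np.random.default_rng(8).standard_normal((10, 1, 1, 300))
        data = np.concatenate([base, 2 * base, 3 * base], axis=2)
        ep = make_epochs(data)
        with pytest.raises(ValueError, match="rank"):
            principal_component_reduce(ep, 2)


class TestIdentifyBands:
    def test_injected_bands_recovered_with_signs(self):
        rng = np.random.default_rng(9)
        freqs = np.arange(4.0, 121.0, 2.0)
        nsub = 15
        base = 10 + 0.3 * rng.standard_normal((nsub, freqs.size))
        task = base + 0.2 * rng.standard_normal((nsub, freqs.size))
        task[:, (freqs >= 12) & (freqs <= 32)] -= 1.0
        task[:, (freqs >= 64) & (freqs <= 88)] += 1.0
        bands = identify_bands(task, base, freqs, n_perm=1000, seed=0)
        signs = {s for _, _, s in bands}
        assert signs == {1, -1}
        neg = next(b for b in bands if b[2] == -1)
        assert neg[0] >= 8 and neg[1] <= 36  # covers the beta suppression

    def test_identical_spectra_give_no_bands(self):
        rng = np.random.default_rng(10)
        freqs = np.arange(4.0, 121.0, 2.0)
        spectra = 10 + 0.3 * rng.standard_normal((12, freqs.size))
        assert identify_bands(spectra, spectra.copy(), freqs,
                              n_perm=500, seed=1) == []

    def test_single_subject_rejected(self):
        freqs = np.arange(4.0, 20.0, 2.0)
        with pytest.raises(ValueError):
            identify_bands(np.ones((1, freqs.size)),
                           np.ones((1, freqs.size)), freqs)
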