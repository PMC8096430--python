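"""Nonparametric conditional Granger causality and directed asymmetry.

The cross-spectral density of the source blocks (two principal components
per source) over the temporal region of interest is factorized into a
minimum-phase transfer function and an innovation covariance with Wilson's
iterative spectral matrix factorization; frequency-resolved conditional
Granger causality (cGC) from a source block X to a target block Y given the
remaining blocks Z follows Geweke's construction from two factorizations
(the full set and the set without X), in the blockwise determinant form.
Estimation bias is quantified by shuffling the trial correspondence of the
source block, which preserves all autospectra while destroying cross-source
covariance.  The directed influence asymmetry index
DAI = (GC(A->B) - GC(B->A)) / (GC(A->B) + GC(B->A)) summarizes the net
direction per frequency and is correlated with stopping performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cluster import ClusterResult, cluster_permutation_test
from .containers import SourceEpochs
from .spectral import CSDMatrix, _tapered_fft, principal_component_reduce

DEFAULT_WINDOWS = ((-100.0, 150.0), (0.0, 250.0), (100.0, 350.0),
                   (200.0, 450.0), (300.0, 550.0), (400.0, 650.0))


# ---------------------------------------------------------------------------
# Wilson spectral matrix factorization
# ---------------------------------------------------------------------------

@dataclass
class FactorizationResult:
    freq_grid: np.ndarray
    transfer: np.ndarray       # (n_freq, m, m) minimum-phase H
    noise_cov: np.ndarray      # (m, m) innovation covariance
    iterations: int
    residual: float


def _two_sided(S1: np.ndarray) -> np.ndarray:
    """Extend a 0..Nyquist CSD to the full FFT grid (S(-f) = S(f)*)."""
    nf, m, _ = S1.shape
    nfft = 2 * (nf - 1)
    S = np.empty((nfft, m, m), dtype=complex)
    S[:nf] = S1
    S[nf:] = S1[1:-1][::-1].conj()
    return S


def wilson_factorize(csd: CSDMatrix | np.ndarray, freq_grid=None,
                     tol: float = 1e-9, max_iter: int = 200,
                     rec_tol: float = 1e-3,
                     loading: float = 1e-8) -> FactorizationResult:
    """Wilson's iterative spectral factorization S(f) = H(f) Sigma H*(f).

    The CSD must live on a full regular grid from 0 to the Nyquist
    frequency.  Iteration stops when the relative step change falls below
    ``tol`` or after ``max_iter`` sweeps; convergence is then judged by the
    relative reconstruction error of H Sigma H* against the input CSD,
    which must be below ``rec_tol`` or an error is raised.  Near-singular
    CSDs are regularized by diagonal loading (``loading`` times the mean
    diagonal power).
    """
    if isinstance(csd, CSDMatrix):
        S1 = csd.matrices.copy()
        freq_grid = csd.freq_grid
    else:
        S1 = np.asarray(csd, dtype=complex).copy()
        if freq_grid is None:
            raise ValueError("freq_grid required for raw CSD arrays")
    nf, m, _ = S1.shape
    mean_power = float(np.real(np.trace(S1.sum(axis=0)))) / (nf * m)
    S1 += loading * mean_power * np.eye(m)[None]

    S = _two_sided(S1)
    nfft = S.shape[0]
    gam = np.real(np.fft.ifft(S, axis=0))
    gam0 = gam[0]
    try:
        h = np.linalg.cholesky(gam0).T  # upper triangular factor
    except np.linalg.LinAlgError:
        gam0 = gam0 + 1e-6 * np.trace(gam0) / m * np.eye(m)
        h = np.linalg.cholesky(gam0).T
    psi = np.broadcast_to(h.astype(complex), S.shape).copy()

    eye = np.eye(m)
    residual = np.inf
    prev = np.inf
    for it in range(1, max_iter + 1):
        # g = psi^{-1} S psi^{-H} + I
        a = np.linalg.solve(psi, S)
        g = np.linalg.solve(psi, a.conj().transpose(0, 2, 1)) \
            .conj().transpose(0, 2, 1)
        g = g + eye[None]
        # causal part ("plus operator")
        gm = np.fft.ifft(g, axis=0)
        beta0 = 0.5 * gm[0]
        gm[0] = np.triu(beta0)
        gm[nf:] = 0.0
        gp = np.fft.fft(gm, axis=0)
        psi_new = psi @ gp
        delta = np.abs(psi_new - psi).max()
        scale = max(np.abs(psi).max(), 1e-300)
        psi = psi_new
        residual = delta / scale
        # stop on tolerance or when the step size stalls (limit cycle)
        if residual < tol or (it >= 10 and residual >= 0.999 * prev):
            break
        prev = residual

    gamtmp = np.real(np.fft.ifft(psi, axis=0))
    A0 = gamtmp[0]
    sigma = A0 @ A0.T
    H = psi[:nf] @ np.linalg.inv(A0)
    recon = H @ sigma @ H.conj().transpose(0, 2, 1)
    rec_err = float(np.linalg.norm(recon - S1) / max(np.linalg.norm(S1),
                                                     1e-300))
    if rec_err > rec_tol:
        raise RuntimeError(
            f"Wilson factorization did not converge: reconstruction error "
            f"{rec_err:.2e} after {it} iterations (step residual "
            f"{residual:.2e})")
    return FactorizationResult(freq_grid=np.asarray(freq_grid),
                               transfer=H, noise_cov=sigma,
                               iterations=it, residual=rec_err)


# ---------------------------------------------------------------------------
# blockwise conditional Granger causality
# ---------------------------------------------------------------------------

def _conditional_gc(S_full: np.ndarray, freq_grid, tgt: list, src: list,
                    cond: list, reduced: FactorizationResult | None = None,
                    **factor_kw) -> np.ndarray:
    """Geweke conditional GC of block ``src`` onto ``tgt`` given ``cond``.

    ``S_full`` is (n_freq, m, m) on the full 0..Nyquist grid; ``tgt``,
    ``src`` and ``cond`` are channel index lists.  ``reduced`` may carry a
    precomputed factorization of the reduced CSD with channels ordered
    [tgt, cond] (reused across bias surrogates, which leave it unchanged).
    """
    order = tgt + cond + src          # target first, source last
    ny, nz = len(tgt), len(cond)
    S_ord = S_full[np.ix_(np.arange(S_full.shape[0]), order, order)]

    if reduced is None:
        red_idx = tgt + cond
        S_red = S_full[np.ix_(np.arange(S_full.shape[0]), red_idx, red_idx)]
        reduced = wilson_factorize(S_red, freq_grid, **factor_kw)
    sigma_r_yy = reduced.noise_cov[:ny, :ny]

    full = wilson_factorize(S_ord, freq_grid, **factor_kw)
    H, sig = full.transfer, full.noise_cov
    m = sig.shape[0]

    # rotate so target-block innovations are uncorrelated with the rest
    L = np.zeros((m, m))
    L[ny:, :ny] = -sig[ny:, :ny] @ np.linalg.inv(sig[:ny, :ny])
    P = np.eye(m) + L
    Hn = H @ (np.eye(m) - L)          # H P^{-1}; L is nilpotent

    # embed the reduced transfer with identity on the source block
    nf = H.shape[0]
    G_emb = np.broadcast_to(np.eye(m, dtype=complex), (nf, m, m)).copy()
    G_emb[:, :ny + nz, :ny + nz] = reduced.transfer
    Q = np.linalg.solve(G_emb, Hn)

    Qyy = Q[:, :ny, :ny]
    intrinsic = Qyy @ sig[:ny, :ny] @ Qyy.conj().transpose(0, 2, 1)
    num = np.real(np.linalg.det(sigma_r_yy[None]))
    den = np.real(np.linalg.det(intrinsic))
    den = np.maximum(den, 1e-300)
    return np.log(np.maximum(num, 1e-300) / den)


@dataclass
class GCSpectrum:
    subject: object
    link: tuple
    condition: str
    freq_grid: np.ndarray
    values: np.ndarray
    bias_mean: float | None = None
    bias_975: float | None = None
    significant: bool | None = None

    def band_mean(self, band=(8.0, 44.0)) -> float:
        sel = (self.freq_grid >= band[0]) & (self.freq_grid <= band[1])
        return float(self.values[sel].mean())

    def at(self, freqs) -> np.ndarray:
        """Linear interpolation of the spectrum at the given frequencies."""
        return np.interp(np.asarray(freqs, dtype=float),
                         self.freq_grid, self.values)


def _block_setup(epochs: SourceEpochs, link, conditioning, n_pcs):
    if conditioning is None:
        conditioning = [s for s in epochs.sources if s not in link]
    srcs = [link[0], link[1], *conditioning]
    sub = epochs.select_sources(srcs)
    if sub.n_components > n_pcs:
        sub = principal_component_reduce(sub, n_pcs)
    npc = sub.n_components
    blocks = {s: list(range(i * npc, (i + 1) * npc))
              for i, s in enumerate(srcs)}
    cond_idx = [c for s in conditioning for c in blocks[s]]
    return sub, blocks, cond_idx, conditioning


def _windowed_fft(sub: SourceEpochs, window, half_bandwidth, nfft):
    data, _ = sub.signal_locked(*window)
    nt, ns, nc, nsamp = data.shape
    x = data.reshape(nt, ns * nc, nsamp)
    x = x - x.mean(axis=-1, keepdims=True)
    if nfft is None:
        nfft = max(256, int(2 ** np.ceil(np.log2(nsamp))))
    return _tapered_fft(x, sub.sfreq, half_bandwidth, nfft)


def conditional_gc_spectrum(epochs: SourceEpochs, link: tuple,
                            conditioning=None, window=(100.0, 350.0),
                            half_bandwidth: float = 5.0,
                            nfft: int | None = 256, n_pcs: int = 2,
                            condition: str | None = None,
                            subject=None, **factor_kw) -> GCSpectrum:
    """Conditional GC spectrum for a directed link X -> Y given Z.

    ``epochs`` should already be restricted to one condition's trials
    (pass ``condition`` to subset by outcome here).  Each source enters as
    a block of its first ``n_pcs`` principal components; with no
    conditioning sources the measure degrades to pairwise GC.
    """
    if condition is not None:
        epochs = epochs.select_outcome(condition)
    sub, blocks, cond_idx, conditioning = _block_setup(
        epochs, link, conditioning, n_pcs)
    spec, freqs, k = _windowed_fft(sub, window, half_bandwidth, nfft)
    nt = spec.shape[0]
    csd = np.einsum("rkcf,rkdf->fcd", spec, spec.conj()) / (nt * k)
    vals = _conditional_gc(csd, freqs, tgt=blocks[link[1]],
                           src=blocks[link[0]], cond=cond_idx, **factor_kw)
    if subject is None and len(sub.trials):
        subject = sub.trials["subject"].iloc[0]
    return GCSpectrum(subject=subject, link=tuple(link),
                      condition=condition or "", freq_grid=freqs,
                      values=vals)


def gc_bias_threshold(epochs: SourceEpochs, link: tuple, conditioning=None,
                      condition: str | None = None, n_perm: int = 1000,
                      band: tuple = (8.0, 44.0), seed: int = 0,
                      window=(100.0, 350.0), half_bandwidth: float = 5.0,
                      nfft: int | None = 256, n_pcs: int = 2,
                      **factor_kw) -> GCSpectrum:
    """Bias estimate and significance for one directed link and condition.

    Surrogates shuffle the trial order of the source block relative to the
    target and conditioning blocks, destroying cross-source covariance
    while preserving every autospectrum; the link is significant when the
    observed band-averaged cGC exceeds the 97.5th percentile of the
    surrogate distribution (p < 0.05 Bonferroni-corrected for the two
    source-target pairs tested).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    if condition is not None:
        epochs = epochs.select_outcome(condition)
    sub, blocks, cond_idx, conditioning = _block_setup(
        epochs, link, conditioning, n_pcs)
    if sub.n_trials < 20:
        raise ValueError(f"need at least 20 trials, have {sub.n_trials}")
    spec, freqs, k = _windowed_fft(sub, window, half_bandwidth, nfft)
    nt = spec.shape[0]
    csd = np.einsum("rkcf,rkdf->fcd", spec, spec.conj()) / (nt * k)

    tgt, src = blocks[link[1]], blocks[link[0]]
    red_idx = tgt + cond_idx
    nf_axis = np.arange(csd.shape[0])
    S_red = csd[np.ix_(nf_axis, red_idx, red_idx)]
    reduced = wilson_factorize(S_red, freqs, **factor_kw)

    obs = _conditional_gc(csd, freqs, tgt, src, cond_idx, reduced=reduced,
                          **factor_kw)
    bsel = (freqs >= band[0]) & (freqs <= band[1])
    obs_band = float(obs[bsel].mean())

    other = [c for c in range(csd.shape[1]) if c not in src]
    rng = np.random.default_rng(seed)
    surr_means = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(nt)
        S = csd.copy()
        cross = np.einsum("rkcf,rkdf->fcd", spec[perm][:, :, src, :],
                          spec[:, :, other, :].conj()) / (nt * k)
        S[np.ix_(nf_axis, src, other)] = cross
        S[np.ix_(nf_axis, other, src)] = cross.conj().transpose(0, 2, 1)
        vals = _conditional_gc(S, freqs, tgt, src, cond_idx, reduced=reduced,
                               **factor_kw)
        surr_means[p] = vals[bsel].mean()

    bias_975 = float(np.percentile(surr_means, 97.5))
    out = GCSpectrum(subject=sub.trials["subject"].iloc[0]
                     if len(sub.trials) else None,
                     link=tuple(link), condition=condition or "",
                     freq_grid=freqs, values=obs,
                     bias_mean=float(surr_means.mean()),
                     bias_975=bias_975,
                     significant=bool(obs_band > bias_975))
    return out


# ---------------------------------------------------------------------------
# group statistics, DAI and sliding windows
# ---------------------------------------------------------------------------

def group_contrast(gc_sstop: list, gc_acgo: list, freq_range=(8.0, 44.0),
                   alpha_cluster: float = 0.05, n_perm: int = 50_000,
                   seed: int = 0, n_links: int = 2,
                   require_significant: bool = True) -> ClusterResult:
    """Cluster permutation contrast of paired cGC spectra across conditions.

    Subjects enter when at least one of their two condition links is
    reliably above bias (``significant`` flag), per the retention rule.
    Cluster p values are compared to 0.025 after Bonferroni correction for
    ``n_links`` directed links.
    """
    pairs = []
    for s, a in zip(gc_sstop, gc_acgo):
        if require_significant and not (
                (s.significant or a.significant)
                or (s.significant is None and a.significant is None)):
            continue
        pairs.append((s, a))
    if len(pairs) < 2:
        raise ValueError("fewer than 2 retained subjects")
    freqs = pairs[0][0].freq_grid
    sel = (freqs >= freq_range[0]) & (freqs <= freq_range[1])
    a = np.stack([p[0].values[sel] for p in pairs])
    b = np.stack([p[1].values[sel] for p in pairs])
    res = cluster_permutation_test(a, b, adjacency="1d",
                                   alpha_cluster=alpha_cluster,
                                   n_perm=n_perm, seed=seed,
                                   alpha=0.025 / n_links)
    res.freqs = freqs[sel]
    for c in res.clusters:
        c.p_corrected = min(1.0, c.p_value * n_links)
    return res


def compute_dai(gc_ab: float, gc_ba: float) -> float:
    """Directed influence asymmetry index (GC_ab - GC_ba)/(GC_ab + GC_ba)."""
    gc_ab = max(float(gc_ab), 0.0)
    gc_ba = max(float(gc_ba), 0.0)
    if gc_ab + gc_ba == 0:
        return float("nan")
    return (gc_ab - gc_ba) / (gc_ab + gc_ba)


def dai_table(gc_ab: GCSpectrum, gc_ba: GCSpectrum, freqs) -> np.ndarray:
    """DAI at the given frequencies from two opposite-direction spectra."""
    va, vb = gc_ab.at(freqs), gc_ba.at(freqs)
    return np.array([compute_dai(x, y) for x, y in zip(va, vb)])


def dai_ssrt_correlation(dai: np.ndarray, ssrt: np.ndarray,
                         freqs=None, n_boot: int = 1000, seed: int = 0,
                         n_freq_tests: int = 6):
    """Pearson correlation of DAI with SSRT per frequency, bootstrap CI.

    ``dai`` is (subjects, n_freq); the confidence level is
    100*(1 - 0.05/n_freq_tests)% -- 99.17% for the six discrete
    frequencies tested -- and a frequency is significant when its CI
    excludes zero.  Returns a list of dicts per frequency.
    """
    dai = np.atleast_2d(np.asarray(dai, dtype=float))
    ssrt = np.asarray(ssrt, dtype=float)
    if dai.shape[0] != ssrt.size:
        dai = dai.T
    n, nf = dai.shape
    if n < 10:
        raise ValueError("need at least 10 subjects")
    if np.std(ssrt) == 0:
        raise ValueError("degenerate SSRT variance")
    level = 100.0 * (1.0 - 0.05 / n_freq_tests)
    lo_q, hi_q = (100.0 - level) / 2.0, 100.0 - (100.0 - level) / 2.0
    rng = np.random.default_rng(seed)
    out = []
    for fi in range(nf):
        x = dai[:, fi]
        if np.std(x) == 0:
            raise ValueError("degenerate DAI variance")
        r = float(np.corrcoef(x, ssrt)[0, 1])
        boots = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            if np.std(x[idx]) == 0 or np.std(ssrt[idx]) == 0:
                boots[b] = 0.0
            else:
                boots[b] = np.corrcoef(x[idx], ssrt[idx])[0, 1]
        ci = (float(np.percentile(boots, lo_q)),
              float(np.percentile(boots, hi_q)))
        out.append({"freq": None if freqs is None else float(freqs[fi]),
                    "r": r, "ci": ci, "ci_level": level,
                    "significant": bool(ci[0] > 0 or ci[1] < 0)})
    return out


def sliding_window_contrast(cohort: list, link: tuple, conditioning=None,
                            windows=DEFAULT_WINDOWS, n_perm: int = 5000,
                            seed: int = 0, n_links: int = 2,
                            **gc_kw) -> dict:
    """Group contrast per sliding window around the temporal ROI.

    ``cohort`` is a list of per-subject epoch sets holding both sSTOP and
    cAC-GO trials.  Each window's cluster p values are Bonferroni-corrected
    for the number of windows times the number of directed links tested.
    Windows that do not fit the epoch span are skipped (reported as None).
    """
    results = {}
    n_tests = len(windows) * n_links
    for win in windows:
        gc_s, gc_a = [], []
        try:
            for ep in cohort:
                gc_s.append(conditional_gc_spectrum(
                    ep, link, conditioning, window=win,
                    condition="sSTOP", **gc_kw))
                gc_a.append(conditional_gc_spectrum(
                    ep, link, conditioning, window=win,
                    condition="cAC-GO", **gc_kw))
        except ValueError:
            results[win] = None  # window outside the epoch span
            continue
        res = group_contrast(gc_s, gc_a, n_perm=n_perm, seed=seed,
                             n_links=1, require_significant=False)
        res.alpha = 0.05 / n_tests
        for c in res.clusters:
            c.p_corrected = min(1.0, c.p_value * n_tests)
        res.significance_mask = np.zeros_like(res.significance_mask)
        for c in res.clusters:
            if c.p_value <= res.alpha:
                res.significance_mask.ravel()[c.members] = True
        results[win] = res
    return results
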