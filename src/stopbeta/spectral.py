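"""Multitaper spectra, cross-spectral density, TFRs and baseline z-scoring.

Conventions: times in ms, 0 = STOP/AC-GO signal onset for task windows; the
baseline is GO-locked and ends 100 ms before the GO cue.  Analysis windows
are extended to an integer number of cycles of the band's center frequency
to avoid spectral leakage (100-350 ms at 22 Hz becomes 100-373 ms).  The
multitaper taper count follows the standard floor(2*T*W) - 1 rule, which
yields four Slepian tapers for the beta band (T = 0.273 s, W = 10 Hz) and
five for the gamma band (W = 12 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy.signal.windows import dpss, hann

from .cluster import cluster_permutation_test
from .containers import SourceEpochs


@dataclass
class AnalysisParams:
    """Windows and bands of the analysis chain (ms / Hz)."""
    troi: tuple = (100.0, 350.0)       # signal-locked, end = SSRT_max
    baseline_offset: float = -100.0    # baseline end relative to GO onset
    beta_band: tuple = (12.0, 32.0)
    gamma_band: tuple = (64.0, 88.0)
    tfr_freqs: tuple = (8.0, 44.0)
    tfr_freq_step: float = 2.0
    tfr_cycles: float = 3.0
    tfr_time_step: float = 10.0
    sensor_freq_range: tuple = (4.0, 120.0)

    def __post_init__(self):
        if self.troi[0] >= self.troi[1]:
            raise ValueError("troi start must precede end")

    def baseline_window(self, duration: float) -> tuple:
        """GO-locked baseline window of the given duration (ms)."""
        return (self.baseline_offset - duration, self.baseline_offset)

    @property
    def tfr_freq_grid(self) -> np.ndarray:
        lo, hi = self.tfr_freqs
        return np.arange(lo, hi + 1e-9, self.tfr_freq_step)


def cycle_align_window(nominal_window: tuple, center_freq: float) -> tuple:
    """Extend a window to the smallest integer number of cycles.

    The start is unchanged; the duration grows to the smallest integer
    multiple of one cycle of ``center_freq`` that covers the nominal
    duration, and the end is rounded to the nearest ms.
    """
    if center_freq <= 0:
        raise ValueError("center frequency must be positive")
    start, end = nominal_window
    duration = end - start
    if duration <= 0:
        raise ValueError("window duration must be positive")
    cycle = 1000.0 / center_freq
    n_cycles = int(np.ceil(duration / cycle - 1e-12))
    return (start, float(round(start + n_cycles * cycle)))


def n_tapers(duration_s: float, half_bandwidth: float) -> int:
    """Slepian taper count floor(2*T*W) - 1 for the given smoothing."""
    k = int(np.floor(2.0 * duration_s * half_bandwidth + 1e-9)) - 1
    if k < 1:
        raise ValueError(
            f"time-bandwidth product 2*T*W = {2 * duration_s * half_bandwidth:.2f} "
            "allows no taper; enlarge the window or the smoothing bandwidth")
    return k


@dataclass
class CSDMatrix:
    """Cross-spectral density on a full 0..Nyquist grid."""
    freq_grid: np.ndarray
    matrices: np.ndarray          # (n_freq, ch, ch), complex, Hermitian
    window_span: tuple
    n_tapers: int
    smoothing: float              # half bandwidth, Hz
    sfreq: float
    channel_names: list = field(default_factory=list)

    def __post_init__(self):
        herm_err = np.abs(self.matrices
                          - self.matrices.conj().transpose(0, 2, 1)).max()
        if herm_err > 1e-8 * max(np.abs(self.matrices).max(), 1e-30):
            raise ValueError("CSD matrices are not Hermitian")


def _tapered_fft(x: np.ndarray, sfreq: float, half_bandwidth: float,
                 nfft: int | None = None):
    """DPSS-tapered FFTs: (trials, tapers, channels, freqs) and freq grid."""
    n = x.shape[-1]
    k = n_tapers(n / sfreq, half_bandwidth)
    tapers = dpss(n, n / sfreq * half_bandwidth, Kmax=k)  # unit energy
    if nfft is None:
        nfft = int(2 ** np.ceil(np.log2(n)))
    xt = x[:, None, :, :] * tapers[None, :, None, :]
    spec = np.fft.rfft(xt, n=nfft, axis=-1)
    freqs = np.fft.rfftfreq(nfft, 1.0 / sfreq)
    # unit-energy tapers: one-sided PSD scaling so band-integrated power
    # matches time-domain variance
    return spec * np.sqrt(2.0 / sfreq), freqs, k


def multitaper_csd(epochs: SourceEpochs, window: tuple, center_freq: float,
                   half_bandwidth: float, nfft: int | None = None,
                   anchor: str = "signal") -> CSDMatrix:
    """Multitaper CSD over a signal-locked (or GO-locked) window.

    Channels are the flattened (source, component) pairs of ``epochs``;
    reduce components first if a per-source block structure is wanted.
    ``center_freq`` documents the band the window was cycle-aligned for.
    """
    if anchor == "signal":
        data, _ = epochs.signal_locked(*window)
    else:
        data, _ = epochs.go_locked(*window)
    nt, ns, nc, nsamp = data.shape
    x = data.reshape(nt, ns * nc, nsamp)
    x = x - x.mean(axis=-1, keepdims=True)
    spec, freqs, k = _tapered_fft(x, epochs.sfreq, half_bandwidth, nfft)
    csd = np.einsum("rkcf,rkdf->fcd", spec, spec.conj()) / (nt * k)
    names = [f"{s}/{c}" for s in epochs.sources for c in range(nc)]
    return CSDMatrix(freq_grid=freqs, matrices=csd, window_span=tuple(window),
                     n_tapers=k, smoothing=half_bandwidth, sfreq=epochs.sfreq,
                     channel_names=names)


# ---------------------------------------------------------------------------
# time-frequency representations
# ---------------------------------------------------------------------------

@dataclass
class TFRData:
    """Single-source time-frequency power with baseline statistics.

    ``power`` is (trials, n_freq, n_time) on a signal-locked ms grid;
    ``baseline_power`` is the per-trial baseline-window mean power per
    frequency, computed GO-locked.
    """
    power: np.ndarray
    freq_grid: np.ndarray
    time_grid: np.ndarray
    baseline_power: np.ndarray   # (trials, n_freq)
    z_scored: bool = False
    source: str = ""

    def average(self) -> np.ndarray:
        return np.nanmean(self.power, axis=0)


def _hanning_tfr(x: np.ndarray, sfreq: float, freqs: np.ndarray,
                 cycles: float):
    """Sliding Hanning-taper power on the native sample grid.

    Edge samples whose window is incomplete are NaN.  Returns
    (trials, n_freq, n_samples).
    """
    nt, nsamp = x.shape
    out = np.full((nt, freqs.size, nsamp), np.nan)
    for fi, f in enumerate(freqs):
        L = int(round(cycles / f * sfreq))
        L = max(L, 3)
        if L > nsamp:
            continue  # frequency undefined for this epoch length
        win = hann(L, sym=False)
        win = win / win.sum()
        t = np.arange(L) / sfreq
        kernel = win * np.exp(-2j * np.pi * f * t)
        conv = sps.fftconvolve(x, kernel[None, ::-1].conj(), mode="same",
                               axes=-1)
        power = 2.0 * np.abs(conv) ** 2
        half = L // 2
        power[:, :half] = np.nan
        if half > 0:
            power[:, -half:] = np.nan
        out[:, fi, :] = power
    return out


def compute_tfr(epochs: SourceEpochs, params: AnalysisParams, source: str,
                tmin: float = -100.0, tmax: float = 700.0,
                component: int = 0) -> TFRData:
    """Hanning-taper TFR of one source, signal-locked, with GO-locked baseline.

    Power at (t, f) comes from a sliding window of ``params.tfr_cycles``
    cycles of f centered at t; the output time grid runs from ``tmin`` to
    ``tmax`` ms after the signal in ``params.tfr_time_step`` steps.  The
    per-trial baseline power (window of tROI length ending
    ``params.baseline_offset`` ms before GO) is stored for z-scoring.
    """
    si = epochs.source_index(source)
    x = epochs.data[:, si, component, :]
    freqs = params.tfr_freq_grid
    lowest = freqs.min()
    if epochs.times.size / epochs.sfreq < params.tfr_cycles / lowest:
        import warnings
        warnings.warn(f"epoch shorter than {params.tfr_cycles} cycles at "
                      f"{lowest} Hz; low frequencies will be undefined",
                      stacklevel=2)
    power = _hanning_tfr(x, epochs.sfreq, freqs, params.tfr_cycles)

    dt = 1000.0 / epochs.sfreq
    t0 = epochs.times[0]
    delays = epochs.trials["delay_ms"].to_numpy(dtype=float)
    if np.isnan(delays).any():
        raise ValueError("all epochs must carry a signal delay for "
                         "signal-locked TFRs")
    time_grid = np.arange(tmin, tmax + 1e-9, params.tfr_time_step)
    # per-trial signal-locked sampling of the native-grid power
    idx = np.round((delays[:, None] + time_grid[None, :] - t0) / dt).astype(int)
    if idx.min() < 0 or idx.max() >= x.shape[-1]:
        raise ValueError("signal-locked TFR window exceeds the epoch span; "
                         "shrink tmin/tmax or extend epoch_span")
    task = np.take_along_axis(power, idx[:, None, :], axis=2)

    duration = params.troi[1] - params.troi[0]
    b0, b1 = params.baseline_window(duration)
    bsel = (epochs.times >= b0 - 1e-9) & (epochs.times <= b1 + 1e-9)
    if not bsel.any():
        raise ValueError("baseline window outside epoch span")
    baseline = np.nanmean(power[:, :, bsel], axis=2)

    return TFRData(power=task, freq_grid=freqs, time_grid=time_grid,
                   baseline_power=baseline, source=source)


def baseline_z_transform(tfr_a: TFRData, tfr_b: TFRData):
    """Condition-wise baseline z-scoring with pooled baseline SD.

    Each condition's power is centered on its own baseline mean and divided
    by the standard deviation of the pooled (both-condition) baseline
    trials, per frequency.  Returns new z-scored (tfr_a, tfr_b).
    """
    if not (np.allclose(tfr_a.freq_grid, tfr_b.freq_grid)
            and np.allclose(tfr_a.time_grid, tfr_b.time_grid)):
        raise ValueError("conditions must share frequency and time grids")
    pooled = np.concatenate([tfr_a.baseline_power, tfr_b.baseline_power])
    sd = pooled.std(axis=0, ddof=1)
    if np.any(sd <= 0) or np.any(~np.isfinite(sd)):
        raise ValueError("zero pooled baseline SD at some frequency")
    out = []
    for tfr in (tfr_a, tfr_b):
        mean = tfr.baseline_power.mean(axis=0)
        z = (tfr.power - mean[None, :, None]) / sd[None, :, None]
        zb = (tfr.baseline_power - mean[None, :]) / sd[None, :]
        out.append(replace(tfr, power=z, baseline_power=zb, z_scored=True))
    return tuple(out)


# ---------------------------------------------------------------------------
# component reduction and band identification
# ---------------------------------------------------------------------------

def principal_component_reduce(epochs: SourceEpochs,
                               n_keep: int) -> SourceEpochs:
    """Project each source onto its top variance directions.

    The component covariance is pooled over trials and samples per source;
    the data are projected onto the leading ``n_keep`` eigenvectors
    (variance-ordered, dominant dipole orientation first).
    """
    nc = epochs.n_components
    if n_keep > nc:
        raise ValueError(f"n_keep={n_keep} exceeds {nc} components")
    nt, ns, _, nsamp = epochs.data.shape
    out = np.empty((nt, ns, n_keep, nsamp))
    for si in range(ns):
        x = epochs.data[:, si].transpose(1, 0, 2).reshape(nc, -1)
        x = x - x.mean(axis=1, keepdims=True)
        cov = x @ x.T / x.shape[1]
        rank = np.linalg.matrix_rank(cov, tol=1e-10 * np.trace(cov) / nc)
        if n_keep > rank:
            raise ValueError(f"source {epochs.sources[si]}: covariance rank "
                             f"{rank} < n_keep={n_keep}")
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1][:n_keep]
        proj = evecs[:, order]
        # fix sign for reproducibility: largest loading positive
        signs = np.sign(proj[np.argmax(np.abs(proj), axis=0),
                             np.arange(n_keep)])
        proj = proj * signs[None, :]
        out[:, si] = np.einsum("ck,tcs->tks", proj, epochs.data[:, si])
    return replace(epochs, data=out)


def identify_bands(task_spectra: np.ndarray, baseline_spectra: np.ndarray,
                   freqs: np.ndarray, alpha_cluster: float = 0.01,
                   n_perm: int = 5000, seed: int = 0) -> list:
    """Find frequency bands where task power differs from baseline.

    Runs the paired cluster permutation test over the frequency axis
    (two-sided, Bonferroni-corrected alpha = 0.01, i.e. cluster masses
    beyond the 99.5th percentile of the permutation distribution) on
    per-subject channel-averaged spectra.  Returns a list of
    ``(f_lo, f_hi, sign)`` bands.
    """
    task_spectra = np.asarray(task_spectra, dtype=float)
    if task_spectra.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    res = cluster_permutation_test(task_spectra, baseline_spectra,
                                   adjacency="1d",
                                   alpha_cluster=alpha_cluster,
                                   n_perm=n_perm, seed=seed, alpha=0.005)
    bands = []
    for c in res.significant:
        lo, hi = freqs[c.members.min()], freqs[c.members.max()]
        bands.append((float(lo), float(hi), 1 if c.mass > 0 else -1))
    return bands
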