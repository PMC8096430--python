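"""Time-resolved decoding of successful stops vs attentional-capture go trials.

Single-source time courses are baseline z-normalized, smoothed (+-10 ms
Gaussian), downsampled to 300 Hz and time-embedded with 14 consecutive
samples -- one beta cycle at the 22 Hz center frequency.  Per iteration,
trials of each condition are randomly averaged into eight supertrials; a
linear max-margin classifier is trained at every time point with one
supertrial per condition held out, rotating over all eight folds, and the
accuracy is averaged over folds and iterations.  Group significance uses a
one-sample cluster permutation test against the 50% chance level inside the
temporal region of interest; individual onsets are extracted from the
low-pass-filtered accuracy time course with a fractional-peak threshold.

The default classifier is a batched dual coordinate-descent solver for the
L1-hinge linear SVM (all time points solved simultaneously); it is the same
optimization problem liblinear solves, and scikit-learn's ``LinearSVC`` is
available as the ``classifier="sklearn"`` option and serves as the
cross-check oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from .cluster import ClusterResult, cluster_permutation_test
from .containers import SourceEpochs
from .latency import OnsetEstimate

EMBED_CENTER_FREQ = 22.0  # Hz; one cycle at 300 Hz -> 14 samples


def embedding_length(sfreq: float, center_freq: float = EMBED_CENTER_FREQ) -> int:
    """Samples per embedded vector: one cycle of the beta center frequency."""
    return int(round(sfreq / center_freq))


@dataclass
class PreparedDecoding:
    """Embedded single-source decoding input.

    ``vectors`` maps source label -> (trials, n_times, embed) arrays whose
    embedding window ends at the labeled time point (causal embedding).
    """
    vectors: dict
    labels: np.ndarray           # outcome per trial
    time_grid: np.ndarray        # ms relative to signal onset
    sfreq: float
    embedding_length: int
    subject: object = None


def prepare_decoding_input(epochs: SourceEpochs,
                           baseline: tuple = (-500.0, 0.0),
                           target_sfreq: float = 300.0,
                           smooth_ms: float = 10.0,
                           window: tuple = (-100.0, 700.0),
                           band: tuple | None = None,
                           component: int = 0) -> PreparedDecoding:
    """Normalize, smooth, downsample and time-embed source signals.

    Each trial and source is z-scored against the 500 ms pre-GO baseline,
    optionally band-pass filtered (one-pass Butterworth, for the
    beta-specificity variant), smoothed with a +-10 ms Gaussian kernel,
    resampled to 300 Hz and embedded with ``embedding_length`` causal
    samples per time point over ``window`` ms around the signal onset.
    """
    x = epochs.data[:, :, component, :]  # (trials, sources, samples)
    bsel = (epochs.times >= baseline[0] - 1e-9) & (epochs.times <= baseline[1] + 1e-9)
    if not bsel.any():
        raise ValueError("baseline window outside epoch span")
    mu = x[:, :, bsel].mean(axis=2, keepdims=True)
    sd = x[:, :, bsel].std(axis=2, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero baseline SD in some trial/source")
    x = (x - mu) / sd

    if band is not None:
        sos = sps.butter(4, band, btype="bandpass", fs=epochs.sfreq,
                         output="sos")
        x = sps.sosfilt(sos, x, axis=-1)  # one-pass (causal) filter

    sigma = smooth_ms / 1000.0 * epochs.sfreq
    x = ndimage.gaussian_filter1d(x, sigma=sigma, axis=-1)

    up, down = (np.array([target_sfreq, epochs.sfreq])
                / np.gcd(int(target_sfreq), int(epochs.sfreq))).astype(int)
    x = sps.resample_poly(x, up, down, axis=-1)
    dt = 1000.0 / target_sfreq
    times = epochs.times[0] + dt * np.arange(x.shape[-1])

    embed = embedding_length(target_sfreq)
    time_grid = np.arange(window[0], window[1] + 1e-9, dt)
    delays = epochs.trials["delay_ms"].to_numpy(dtype=float)
    # sample index of each output time point, per trial (signal-locked)
    idx = np.round((delays[:, None] + time_grid[None, :] - times[0]) / dt
                   ).astype(int)
    if (idx - embed + 1).min() < 0 or idx.max() >= x.shape[-1]:
        raise ValueError("decoding window (with causal embedding) exceeds "
                         "the epoch span")
    offsets = np.arange(-embed + 1, 1)
    gather = idx[:, :, None] + offsets[None, None, :]  # (tr, time, embed)
    vectors = {}
    for si, src in enumerate(epochs.sources):
        xs = x[:, si, :]
        vectors[src] = xs[np.arange(xs.shape[0])[:, None, None], gather]
    labels = epochs.trials["outcome"].to_numpy()
    subject = epochs.trials["subject"].iloc[0] if len(epochs.trials) else None
    return PreparedDecoding(vectors=vectors, labels=labels,
                            time_grid=time_grid, sfreq=target_sfreq,
                            embedding_length=embed, subject=subject)


# ---------------------------------------------------------------------------
# linear max-margin classifier, batched over time points
# ---------------------------------------------------------------------------

def _svm_batch_fit(X: np.ndarray, y: np.ndarray, C: float = 1.0,
                   n_epochs: int = 25, seed: int = 0) -> np.ndarray:
    """Dual coordinate descent for the L1-hinge linear SVM, batched.

    X is (problems, n_samples, n_features); y (+-1) is shared across
    problems.  A constant bias feature is appended (liblinear convention).
    Returns weights (problems, n_features + 1).  Single precision is used
    internally (the dual updates are numerically benign).
    """
    P, n, d = X.shape
    Xa = np.concatenate([X, np.ones((P, n, 1))], axis=2).astype(np.float32)
    Q = np.einsum("pnd,pnd->pn", Xa, Xa)  # diagonal of the Gram matrix
    Q[Q == 0] = 1.0
    yf = y.astype(np.float32)
    alpha = np.zeros((P, n), dtype=np.float32)
    w = np.zeros((P, d + 1), dtype=np.float32)
    rng = np.random.default_rng(seed)
    order = np.arange(n)
    C = np.float32(C)
    for _ in range(n_epochs):
        rng.shuffle(order)
        for i in order:
            g = yf[i] * np.einsum("pd,pd->p", w, Xa[:, i, :]) - np.float32(1)
            a_new = np.clip(alpha[:, i] - g / Q[:, i], np.float32(0), C)
            delta = a_new - alpha[:, i]
            alpha[:, i] = a_new
            w += (delta * yf[i])[:, None] * Xa[:, i, :]
    return w.astype(np.float64)


def _svm_batch_predict(w: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Decision sign for (problems, n_samples, n_features) inputs."""
    scores = np.einsum("pnd,pd->pn", X, w[:, :-1]) + w[:, -1][:, None]
    return np.where(scores >= 0, 1.0, -1.0)


def _sklearn_fold(train_X, train_y, test_X, test_y, C):
    from sklearn.svm import LinearSVC
    correct = np.empty(train_X.shape[0])
    for p in range(train_X.shape[0]):
        clf = LinearSVC(C=C, loss="hinge", max_iter=10000)
        clf.fit(train_X[p], train_y)
        correct[p] = (clf.predict(test_X[p]) == test_y).mean()
    return correct


@dataclass
class AccuracyTimeCourse:
    subject: object
    source: str
    time_grid: np.ndarray
    accuracy: np.ndarray
    baseline_mean: float
    baseline_sd: float
    n_iterations: int
    embedding_length: int


def decode_timecourse(prepared: PreparedDecoding, source: str,
                      conditions: tuple = ("sSTOP", "cAC-GO"),
                      n_supertrials: int = 8, n_iterations: int = 100,
                      C: float = 1.0, seed: int = 0,
                      classifier: str = "batched") -> AccuracyTimeCourse:
    """Supertrial-averaged leave-one-out decoding accuracy per time point.

    Per iteration, each condition's trials are randomly partitioned into
    ``n_supertrials`` near-equal groups and averaged; the classifier is
    trained on all but one supertrial per condition and scored on the
    held-out pair, rotating over all folds.  Accuracy is the mean over
    folds and iterations.
    """
    X = prepared.vectors[source]
    labels = prepared.labels
    m0 = labels == conditions[0]
    m1 = labels == conditions[1]
    if m0.sum() < 2 * n_supertrials or m1.sum() < 2 * n_supertrials:
        raise ValueError(f"need at least {2 * n_supertrials} trials per "
                         f"condition; have {m0.sum()} and {m1.sum()}")
    X0, X1 = X[m0], X[m1]
    # equalize trial counts so both classes' supertrials share noise level
    n_eq = min(X0.shape[0], X1.shape[0])
    T = prepared.time_grid.size
    rng = np.random.default_rng(seed)
    y = np.concatenate([np.ones(n_supertrials - 1),
                        -np.ones(n_supertrials - 1)])
    acc = np.zeros(T)
    ns = n_supertrials
    E = X.shape[2]
    if classifier == "batched":
        # all folds of one iteration share the label vector, so each
        # iteration's ns*T problems are solved in one batched fit
        trains = np.empty((ns, T, 2 * (ns - 1), E))
        tests = np.empty((ns, T, 2, E))
        for _ in range(n_iterations):
            parts0 = np.array_split(rng.permutation(X0.shape[0])[:n_eq], ns)
            parts1 = np.array_split(rng.permutation(X1.shape[0])[:n_eq], ns)
            S0 = np.stack([X0[p].mean(axis=0) for p in parts0])  # (8, T, E)
            S1 = np.stack([X1[p].mean(axis=0) for p in parts1])
            for f in range(ns):
                keep = [k for k in range(ns) if k != f]
                trains[f] = np.concatenate(
                    [S0[keep], S1[keep]]).transpose(1, 0, 2)
                tests[f] = np.stack([S0[f], S1[f]]).transpose(1, 0, 2)
            w = _svm_batch_fit(trains.reshape(ns * T, 2 * (ns - 1), E), y,
                               C=C, seed=int(rng.integers(2 ** 31)))
            pred = _svm_batch_predict(w, tests.reshape(ns * T, 2, E))
            correct = ((pred[:, 0] > 0).astype(float)
                       + (pred[:, 1] < 0).astype(float)) / 2.0
            acc += correct.reshape(ns, T).sum(axis=0)
    else:
        for _ in range(n_iterations):
            parts0 = np.array_split(rng.permutation(X0.shape[0])[:n_eq], ns)
            parts1 = np.array_split(rng.permutation(X1.shape[0])[:n_eq], ns)
            S0 = np.stack([X0[p].mean(axis=0) for p in parts0])
            S1 = np.stack([X1[p].mean(axis=0) for p in parts1])
            for f in range(ns):
                keep = [k for k in range(ns) if k != f]
                train = np.concatenate(
                    [S0[keep], S1[keep]]).transpose(1, 0, 2)
                test = np.stack([S0[f], S1[f]]).transpose(1, 0, 2)
                acc += _sklearn_fold(train, y, test,
                                     np.array([1.0, -1.0]), C)
    acc /= n_iterations * n_supertrials
    base = acc[prepared.time_grid < 0]
    return AccuracyTimeCourse(subject=prepared.subject, source=source,
                              time_grid=prepared.time_grid, accuracy=acc,
                              baseline_mean=float(base.mean()),
                              baseline_sd=float(base.std(ddof=1)),
                              n_iterations=n_iterations,
                              embedding_length=prepared.embedding_length)


# ---------------------------------------------------------------------------
# group statistics and onset extraction
# ---------------------------------------------------------------------------

def above_chance_cluster_test(cohort: list, troi: tuple = (100.0, 350.0),
                              n_perm: int = 10_000, seed: int = 0,
                              n_boot: int = 1000):
    """Cluster test of group accuracy against the 50% chance level.

    One-sample (sign-flip) cluster permutation over the tROI time points.
    Returns ``(ClusterResult, earliest_ms, ci)`` where ``earliest_ms`` is
    the first significant time point (NaN if none) and ``ci`` the bootstrap
    95% confidence band of the mean accuracy per tROI time point.
    """
    if len(cohort) < 5:
        raise ValueError("need at least 5 subjects")
    t = cohort[0].time_grid
    sel = (t >= troi[0] - 1e-9) & (t <= troi[1] + 1e-9)
    acc = np.stack([c.accuracy[sel] for c in cohort])
    res = cluster_permutation_test(acc, 0.5, adjacency="1d",
                                   alpha_cluster=0.05, n_perm=n_perm,
                                   seed=seed, alpha=0.05)
    troi_t = t[sel]
    earliest = float("nan")
    if res.significance_mask.any():
        earliest = float(troi_t[np.flatnonzero(res.significance_mask)[0]])
    rng = np.random.default_rng(seed + 1)
    boots = np.empty((n_boot, troi_t.size))
    n = acc.shape[0]
    for b in range(n_boot):
        boots[b] = acc[rng.integers(0, n, n)].mean(axis=0)
    ci = np.percentile(boots, [2.5, 97.5], axis=0)
    return res, earliest, ci


def decoding_onset(acc: AccuracyTimeCourse, sd_multiplier: float = 1.0,
                   fraction: float = 0.25, troi: tuple = (100.0, 350.0),
                   lowpass_hz: float = 10.0) -> OnsetEstimate:
    """Fractional-threshold onset of the decoding accuracy peak.

    The accuracy series is zero-phase low-pass filtered at 10 Hz; the peak
    is the first tROI local maximum exceeding the baseline mean plus
    ``sd_multiplier`` baseline SDs, falling back to the median time of tROI
    points above the series' 95th percentile.  From the peak, the onset is
    found by walking backward to the earliest point of the final stretch
    that exceeds baseline mean + ``fraction`` * (peak - baseline mean).
    Subjects with no qualifying peak are flagged for exclusion.
    """
    t = acc.time_grid
    fs = 1000.0 / float(np.median(np.diff(t)))
    sos = sps.butter(4, lowpass_hz, btype="lowpass", fs=fs, output="sos")
    series = sps.sosfiltfilt(sos, acc.accuracy)
    base_mask = t < 0
    base_mean = float(series[base_mask].mean())
    base_sd = float(series[base_mask].std(ddof=1))
    in_roi = (t >= troi[0] - 1e-9) & (t <= troi[1] + 1e-9)
    roi_idx = np.flatnonzero(in_roi)

    peak_idx = None
    level = base_mean + sd_multiplier * base_sd
    for i in roi_idx:
        if series[i] <= level:
            continue
        left = series[i - 1] if i > 0 else -np.inf
        right = series[i + 1] if i < series.size - 1 else -np.inf
        if series[i] > left and series[i] >= right:
            peak_idx = i
            break
    if peak_idx is None:
        # fallback: median time of tROI points beyond the 95th percentile
        q95 = np.percentile(series, 95)
        cand = roi_idx[series[roi_idx] > q95]
        if cand.size == 0:
            return OnsetEstimate(subject=acc.subject, source=acc.source,
                                 onset_ms=float("nan"), peak_ms=float("nan"),
                                 peak_value=float("nan"), pre_peak_min=base_mean,
                                 threshold_fraction=fraction, excluded=True)
        peak_idx = int(np.median(cand))

    peak_val = float(series[peak_idx])
    threshold = base_mean + fraction * (peak_val - base_mean)
    onset_idx = peak_idx
    i = peak_idx
    while i > 0 and series[i - 1] > threshold:
        i -= 1
        onset_idx = i
    return OnsetEstimate(subject=acc.subject, source=acc.source,
                         onset_ms=float(t[onset_idx]),
                         peak_ms=float(t[peak_idx]), peak_value=peak_val,
                         pre_peak_min=base_mean,
                         threshold_fraction=fraction)
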