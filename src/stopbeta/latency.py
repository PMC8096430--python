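"""Onset-latency estimation from beta-band power difference time courses.

Per subject and source, the z-scored sSTOP and cAC-GO TFRs are differenced,
averaged over the beta band and smoothed; the onset is the time at which the
series first exceeds a fractional threshold of the range between the first
positive peak inside the temporal region of interest and the (nonnegative)
pre-peak minimum.  Group-level onset differences between sources are tested
with a paired permutation test on the mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import TFRData


@dataclass
class OnsetEstimate:
    subject: object
    source: str
    onset_ms: float          # NaN when undefined
    peak_ms: float
    peak_value: float
    pre_peak_min: float
    threshold_fraction: float
    excluded: bool = False   # no positive peak inside the tROI


def band_power_difference_timecourse(z_sstop: TFRData, z_acgo: TFRData,
                                     band: tuple = (12.0, 32.0),
                                     smooth_ms: float = 90.0) -> np.ndarray:
    """z(sSTOP) - z(cAC-GO), band-averaged and smoothed.

    Band frequencies are averaged after differencing the trial-averaged
    z-scored TFRs; a centered moving average of ``smooth_ms`` width smooths
    the series.  Returns the series on ``z_sstop.time_grid``.
    """
    if not (np.allclose(z_sstop.freq_grid, z_acgo.freq_grid)
            and np.allclose(z_sstop.time_grid, z_acgo.time_grid)):
        raise ValueError("conditions must share grids")
    freqs = z_sstop.freq_grid
    sel = (freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9)
    if not sel.any():
        raise ValueError(f"band {band} outside TFR grid "
                         f"{freqs.min()}..{freqs.max()} Hz")
    diff = z_sstop.average()[sel].mean(axis=0) - z_acgo.average()[sel].mean(axis=0)
    return moving_average(diff, z_sstop.time_grid, smooth_ms)


def moving_average(series: np.ndarray, time_grid: np.ndarray,
                   smooth_ms: float) -> np.ndarray:
    """Centered moving average, NaN-aware, width ``smooth_ms``."""
    if smooth_ms <= 0:
        return series.copy()
    dt = float(np.median(np.diff(time_grid)))
    w = max(1, int(round(smooth_ms / dt)))
    if w % 2 == 0:
        w += 1
    kernel = np.ones(w)
    valid = np.isfinite(series).astype(float)
    filled = np.where(np.isfinite(series), series, 0.0)
    num = np.convolve(filled, kernel, mode="same")
    den = np.convolve(valid, kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def detect_onset(series: np.ndarray, time_grid: np.ndarray,
                 troi: tuple = (100.0, 350.0),
                 threshold_fraction: float = 0.25,
                 subject=None, source: str = "",
                 search_start: float = 0.0) -> OnsetEstimate:
    """Threshold-crossing onset of the first positive peak in the tROI.

    The first strict positive local maximum inside ``troi`` is the peak
    (plateaus take their earliest sample); the pre-peak minimum is the
    series minimum from ``search_start`` ms to the peak, clamped below at
    zero.  The onset is the first time the series exceeds
    ``min + fraction * (peak - min)``.  Without a positive peak the onset is
    undefined and the estimate is flagged for exclusion.
    """
    series = np.asarray(series, dtype=float)
    t = np.asarray(time_grid, dtype=float)
    in_roi = (t >= troi[0] - 1e-9) & (t <= troi[1] + 1e-9)
    roi_idx = np.flatnonzero(in_roi)

    peak_idx = None
    for i in roi_idx:
        v = series[i]
        if not np.isfinite(v) or v <= 0:
            continue
        left = series[i - 1] if i > 0 else -np.inf
        right = series[i + 1] if i < series.size - 1 else -np.inf
        if v > left and v >= right:  # plateau takes the earliest sample
            peak_idx = i
            break
    if peak_idx is None:
        return OnsetEstimate(subject=subject, source=source,
                             onset_ms=float("nan"), peak_ms=float("nan"),
                             peak_value=float("nan"),
                             pre_peak_min=float("nan"),
                             threshold_fraction=threshold_fraction,
                             excluded=True)

    start_idx = int(np.searchsorted(t, search_start - 1e-9))
    pre = series[start_idx:peak_idx + 1]
    pre = pre[np.isfinite(pre)]
    pre_min = max(float(pre.min()), 0.0) if pre.size else 0.0
    peak_val = float(series[peak_idx])
    threshold = pre_min + threshold_fraction * (peak_val - pre_min)

    onset = float(t[peak_idx])
    for i in range(start_idx, peak_idx + 1):
        if np.isfinite(series[i]) and series[i] > threshold:
            onset = float(t[i])
            break
    return OnsetEstimate(subject=subject, source=source, onset_ms=onset,
                         peak_ms=float(t[peak_idx]), peak_value=peak_val,
                         pre_peak_min=pre_min,
                         threshold_fraction=threshold_fraction)


def onset_permutation_test(onsets_a, onsets_b, n_perm: int = 50_000,
                           seed: int = 0):
    """Paired permutation test of onset latencies between two sources.

    The statistic is the mean paired difference; the null swaps source
    labels within subjects (sign flips).  Pairs with an undefined onset must
    be excluded beforehand.  Returns ``(p_value, mean_a, mean_b)``.
    """
    a = np.asarray([o.onset_ms if isinstance(o, OnsetEstimate) else o
                    for o in onsets_a], dtype=float)
    b = np.asarray([o.onset_ms if isinstance(o, OnsetEstimate) else o
                    for o in onsets_b], dtype=float)
    if a.size != b.size:
        raise ValueError("onsets must be paired by subject")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("exclude subjects with undefined onsets first")
    if a.size < 5:
        raise ValueError("need at least 5 subject pairs")
    d = a - b
    obs = d.mean()
    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, d.size))
    null = (flips * d[None, :]).mean(axis=1)
    p = (1.0 + np.sum(np.abs(null) >= abs(obs))) / (n_perm + 1.0)
    return float(p), float(a.mean()), float(b.mean())
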