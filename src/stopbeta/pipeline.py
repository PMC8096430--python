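"""High-level per-subject and cohort drivers chaining the analysis stages.

These helpers run the standard chain on one subject's epochs: select
AC-GO trials matched to the stop process, z-score TFRs against the
GO-locked baseline, extract beta-band contrast time courses and onsets,
and collect the per-subject features (beta-power contrast peaks, DAI,
SSRT) that feed the Bayesian regression.
"""

from __future__ import annotations

import pandas as pd

from .behavior import estimate_ssrt_integration
from .connectivity import conditional_gc_spectrum, dai_table
from .containers import SourceEpochs
from .latency import band_power_difference_timecourse, detect_onset
from .spectral import (AnalysisParams, baseline_z_transform, compute_tfr,
                       principal_component_reduce)


def select_ac_epochs(epochs: SourceEpochs, ssrt_reference: float) -> SourceEpochs:
    """Drop cAC-GO epochs with a post-signal RT below the SSRT reference."""
    tr = epochs.trials
    rt_ac = tr["rt_ms"] - tr["delay_ms"]
    keep = (tr["outcome"] != "cAC-GO") | (rt_ac >= ssrt_reference)
    return epochs.select(keep.to_numpy())


def contrast_timecourse(epochs: SourceEpochs, params: AnalysisParams,
                        source: str, stop_outcome: str = "sSTOP",
                        smooth_ms: float = 90.0, component: int = 0):
    """Smoothed beta-band z-power difference (stop - cAC-GO) for one source.

    Returns ``(series, time_grid)``; ``epochs`` should already have the
    AC-GO selection applied and components reduced (the dominant dipole
    orientation is used).
    """
    ep_stop = epochs.select_outcome(stop_outcome)
    ep_ac = epochs.select_outcome("cAC-GO")
    if ep_stop.n_trials < 2 or ep_ac.n_trials < 2:
        raise ValueError(f"need trials in both {stop_outcome} and cAC-GO")
    tfr_stop = compute_tfr(ep_stop, params, source, component=component)
    tfr_ac = compute_tfr(ep_ac, params, source, component=component)
    z_stop, z_ac = baseline_z_transform(tfr_stop, tfr_ac)
    series = band_power_difference_timecourse(z_stop, z_ac,
                                              band=params.beta_band,
                                              smooth_ms=smooth_ms)
    return series, tfr_stop.time_grid


def subject_onsets(epochs: SourceEpochs, params: AnalysisParams,
                   sources=("rIFG", "pre-SMA"), threshold_fraction=0.25,
                   stop_outcome: str = "sSTOP", smooth_ms: float = 90.0,
                   subject=None):
    """Beta-power contrast onset estimates for the given sources."""
    if epochs.n_components > 1:
        epochs = principal_component_reduce(epochs, 1)
    if subject is None and len(epochs.trials):
        subject = epochs.trials["subject"].iloc[0]
    out = {}
    for src in sources:
        series, tgrid = contrast_timecourse(epochs, params, src,
                                            stop_outcome=stop_outcome,
                                            smooth_ms=smooth_ms)
        out[src] = detect_onset(series, tgrid, troi=params.troi,
                                threshold_fraction=threshold_fraction,
                                subject=subject, source=src)
    return out


def subject_features(epochs: SourceEpochs, trials: pd.DataFrame,
                     subject, params: AnalysisParams | None = None,
                     dai_freq: float = 34.0, ssrt_reference: float | None = None,
                     conditioning=None, gc_kw: dict | None = None) -> dict:
    """Per-subject regression features: contrast peaks, DAI and SSRT.

    Beta-power contrast peaks (stop - cAC-GO) are extracted for rIFG and
    pre-SMA in successful and failed stop trials; ``peak_ok`` requires a
    positive peak inside the tROI for all four.  The DAI is evaluated at
    ``dai_freq`` from the conditional GC of sSTOP trials in both
    directions.
    """
    params = params or AnalysisParams()
    gc_kw = gc_kw or {}
    ep = epochs
    if ssrt_reference is not None:
        ep = select_ac_epochs(ep, ssrt_reference)
    ep1 = principal_component_reduce(ep, 1) if ep.n_components > 1 else ep

    feats = {"subject": subject}
    peak_ok = True
    for src, key in (("rIFG", "rifg"), ("pre-SMA", "presma")):
        for stop_outcome, suffix in (("sSTOP", "s"), ("uSTOP", "f")):
            series, tgrid = contrast_timecourse(ep1, params, src,
                                                stop_outcome=stop_outcome)
            est = detect_onset(series, tgrid, troi=params.troi,
                               subject=subject, source=src)
            feats[f"{key}_{suffix}"] = est.peak_value
            peak_ok &= not est.excluded
    feats["peak_ok"] = bool(peak_ok)

    gc_ab = conditional_gc_spectrum(ep, ("rIFG", "pre-SMA"), conditioning,
                                    condition="sSTOP", subject=subject,
                                    **gc_kw)
    gc_ba = conditional_gc_spectrum(ep, ("pre-SMA", "rIFG"), conditioning,
                                    condition="sSTOP", subject=subject,
                                    **gc_kw)
    feats["dai"] = float(dai_table(gc_ab, gc_ba, [dai_freq])[0])
    feats["ssrt"] = estimate_ssrt_integration(trials, subject)
    return feats


def cohort_features(trials: pd.DataFrame, epochs_by_subject: dict,
                    params: AnalysisParams | None = None,
                    dai_freq: float = 34.0,
                    ssrt_reference: float | None = None,
                    conditioning=None,
                    gc_kw: dict | None = None) -> pd.DataFrame:
    """Feature table over a cohort (one row per subject)."""
    rows = []
    for subject, ep in epochs_by_subject.items():
        rows.append(subject_features(ep, trials, subject, params=params,
                                     dai_freq=dai_freq,
                                     ssrt_reference=ssrt_reference,
                                     conditioning=conditioning, gc_kw=gc_kw))
    return pd.DataFrame(rows)
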