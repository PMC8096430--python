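"""Behavioral analysis: SSRT estimation, summaries, and trial exclusion rules.

The stop-signal reaction time (SSRT) is estimated with the integration
method: the latent stop latency is the point at which the integral of the go
RT distribution equals the observed probability of responding on a STOP
trial, minus the mean stop-signal delay.  On a finite sample this is the RT
at rank ``round(N_GO * p_respond)`` of the ascending go RT distribution
(omissions replaced by the maximum RT), minus the mean SSD over all STOP
trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import validate_trials


def integration_rank(n_go: int, p_respond: float) -> int:
    """1-based rank of the go-RT distribution used by the integration method.

    Round-half-up to the nearest integer, clamped to [1, n_go]; e.g. 1000 GO
    trials at p(respond|signal) = 0.48 select the 480th fastest go RT.
    """
    if n_go < 1:
        raise ValueError("need at least one GO trial")
    rank = int(math.floor(n_go * p_respond + 0.5))
    return min(max(rank, 1), n_go)


def _go_rt_distribution(sub: pd.DataFrame) -> np.ndarray:
    """Ascending go RTs with omissions replaced by the maximum RT."""
    go = sub[sub["condition"] == "GO"]
    if len(go) == 0:
        raise ValueError("subject has no GO trials")
    rts = go["rt_ms"].to_numpy(dtype=float)
    if np.isnan(rts).all():
        raise ValueError("subject has no responded GO trials")
    max_rt = np.nanmax(rts)
    rts = np.where(np.isnan(rts), max_rt, rts)
    return np.sort(rts)


def estimate_ssrt_integration(trials: pd.DataFrame, subject) -> float:
    """Integration-method SSRT (ms) for one subject.

    Returns NaN when p(respond|signal) is 0 or 1 (undefined estimate);
    raises when the subject has no GO or no STOP trials.
    """
    sub = trials[trials["subject"] == subject]
    stop = sub[sub["condition"] == "STOP"]
    if len(stop) == 0:
        raise ValueError(f"subject {subject} has no STOP trials")
    p_respond = float((stop["outcome"] == "uSTOP").mean())
    rts = _go_rt_distribution(sub)
    if p_respond in (0.0, 1.0):
        return float("nan")
    rank = integration_rank(rts.size, p_respond)
    mean_ssd = float(stop["delay_ms"].mean())
    return float(rts[rank - 1] - mean_ssd)


@dataclass
class BehavioralSummary:
    """Per-subject behavioral summary with exclusion flags."""
    subject: object
    p_respond: float
    mean_ssd: float
    mean_ssd_sstop: float
    mean_ssd_ustop: float
    mean_acsd: float
    rt_cgo: float
    rt_cacgo: float
    rt_ustop: float
    omission_rate_go: float
    omission_rate_acgo: float
    ssrt: float
    rt_ac_percentiles: dict = field(default_factory=dict)
    exclusion_flags: set = field(default_factory=set)


def behavioral_summary(trials: pd.DataFrame) -> list[BehavioralSummary]:
    """Summaries per subject with the study's exclusion rules applied.

    Flags ``low_stop_rate`` when p(respond|signal) < 0.40 and
    ``race_model_violation`` when the mean uSTOP RT exceeds the mean cGO RT
    (the race model requires unsuccessful stops to come from the fast tail
    of the go distribution); ``undefined_ssrt`` when p_respond is 0 or 1.
    """
    validate_trials(trials)
    out = []
    for subject, sub in trials.groupby("subject"):
        stop = sub[sub["condition"] == "STOP"]
        go = sub[sub["condition"] == "GO"]
        ac = sub[sub["condition"] == "AC-GO"]
        flags = set()
        if len(stop) == 0 or len(go) == 0:
            flags.add("missing_condition")
            p_respond = float("nan")
            ssrt = float("nan")
        else:
            p_respond = float((stop["outcome"] == "uSTOP").mean())
            ssrt = estimate_ssrt_integration(trials, subject)
        if np.isnan(ssrt):
            flags.add("undefined_ssrt")
        if p_respond < 0.40:
            flags.add("low_stop_rate")

        def _mean(frame, col="rt_ms"):
            vals = frame[col].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            return float(vals.mean()) if vals.size else float("nan")

        rt_cgo = _mean(go[go["outcome"] == "cGO"])
        rt_ustop = _mean(stop[stop["outcome"] == "uSTOP"])
        rt_cacgo = _mean(ac[ac["outcome"] == "cAC-GO"])
        if np.isfinite(rt_ustop) and np.isfinite(rt_cgo) and rt_ustop > rt_cgo:
            flags.add("race_model_violation")

        rt_ac = (ac.loc[ac["outcome"] == "cAC-GO", "rt_ms"]
                 - ac.loc[ac["outcome"] == "cAC-GO", "delay_ms"]).to_numpy()
        rt_ac = rt_ac[~np.isnan(rt_ac)]
        percentiles = {}
        if rt_ac.size:
            percentiles = {10: float(np.percentile(rt_ac, 10)),
                           50: float(np.percentile(rt_ac, 50))}

        out.append(BehavioralSummary(
            subject=subject,
            p_respond=p_respond,
            mean_ssd=_mean(stop, "delay_ms"),
            mean_ssd_sstop=_mean(stop[stop["outcome"] == "sSTOP"], "delay_ms"),
            mean_ssd_ustop=_mean(stop[stop["outcome"] == "uSTOP"], "delay_ms"),
            mean_acsd=_mean(ac, "delay_ms"),
            rt_cgo=rt_cgo,
            rt_cacgo=rt_cacgo,
            rt_ustop=rt_ustop,
            omission_rate_go=float((go["outcome"] == "omission").mean())
            if len(go) else float("nan"),
            omission_rate_acgo=float((ac["outcome"] == "acOmission").mean())
            if len(ac) else float("nan"),
            ssrt=ssrt,
            rt_ac_percentiles=percentiles,
            exclusion_flags=flags,
        ))
    return out


def summary_frame(summaries: list[BehavioralSummary]) -> pd.DataFrame:
    """Tabulate summaries (one row per subject) for TSV export."""
    rows = []
    for s in summaries:
        row = {k: v for k, v in vars(s).items()
               if k not in ("rt_ac_percentiles", "exclusion_flags")}
        row["rt_ac_p10"] = s.rt_ac_percentiles.get(10, float("nan"))
        row["rt_ac_p50"] = s.rt_ac_percentiles.get(50, float("nan"))
        row["exclusion_flags"] = ",".join(sorted(s.exclusion_flags))
        rows.append(row)
    return pd.DataFrame(rows)


def select_ac_trials(trials: pd.DataFrame, ssrt_reference: float):
    """Drop AC-GO trials whose post-signal RT undercuts the SSRT reference.

    The attentional-capture go RT is ``rt_ms - delay_ms``; correct AC-GO
    trials with RT_AC-GO below ``ssrt_reference`` (typically the group median
    SSRT) are removed so that, under the race model, the retained trials
    match successful stops in go-process speed.  All other trial types pass
    through untouched.

    Returns
    -------
    (subset, report)
        ``report`` holds the retained fraction and the 10% / 50% percentiles
        of the retained RT_AC-GO per subject.
    """
    validate_trials(trials)
    is_cac = trials["outcome"] == "cAC-GO"
    rt_ac = trials["rt_ms"] - trials["delay_ms"]
    keep = ~is_cac | (rt_ac >= ssrt_reference)
    report = {}
    for subject, sub_mask in trials.groupby("subject").groups.items():
        m_cac = is_cac[sub_mask]
        if m_cac.sum() == 0:
            continue
        kept = keep[sub_mask] & m_cac
        if kept.sum() == 0:
            raise ValueError(
                f"subject {subject}: no cAC-GO trials survive the "
                f"RT_AC-GO >= {ssrt_reference} ms selection")
        vals = rt_ac[sub_mask][kept].to_numpy(dtype=float)
        report[subject] = {
            "retained_fraction": float(kept.sum() / m_cac.sum()),
            "p10": float(np.percentile(vals, 10)),
            "p50": float(np.percentile(vals, 50)),
        }
    return trials[keep].reset_index(drop=True), report
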