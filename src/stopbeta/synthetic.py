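"""Ground-truth generators for stop-signal behavior and source-level MEG epochs.

The generator plays the role of the experiment: a race-model subject tracked
by a 1-up/1-down stop-signal-delay staircase produces the behavioral trial
table, and a beta-band oscillatory model of seven cortical sources produces
source-level epochs whose condition contrasts carry a known onset lag
(rIFG leading pre-SMA in successful stop trials), a known directed
rIFG -> pre-SMA coupling, and known brain-behavior coefficients.  Every
downstream stage of the analysis chain can therefore be checked against the
injected parameters.

Model summary
-------------
Behavior.  Go finish times are ex-Gaussian (right-skewed, as empirical RTs);
the stop process is a per-trial Gaussian latency around the subject's true
SSRT, truncated at zero.  On STOP trials a response is emitted iff the go
process finishes before delay + stop latency; the delay then steps down 30 ms
(floored) after an unsuccessful stop and up 30 ms after a successful one.
AC-GO delays follow the same staircase trace without updating it, and AC-GO
responses are the go response delayed by an attentional-capture slowing.

Neural data.  Each source emits a band-limited beta carrier (filtered noise)
multiplied by an amplitude envelope: flat baseline, linear desynchronization
ramp after the GO cue, and -- in successful stop trials -- a recovery ramp
starting at the source's characteristic onset after the signal (rIFG first,
pre-SMA ``onset_lag`` ms later).  A phase-locked, beta-frequency evoked
transient with the same onset carries the condition difference into the time
domain for the decoding route.  Sources are expanded to three dipole
components through fixed mixing weights, and broadband plus component noise
is added.  Optionally a time-and-condition-gated VAR coupling injects a
directed rIFG -> pre-SMA influence for the connectivity stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import SourceEpochs, validate_trials

DEFAULT_SOURCES = ("rIFG", "pre-SMA", "l-IFG", "lAIns", "lMFG", "rPMC", "lPMC")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class StaircaseConfig:
    """1-up/1-down stop-signal-delay staircase parameters (ms)."""
    initial_delay: float = 210.0
    step: float = 30.0
    min_delay: float = 40.0
    max_rt: float = 1000.0

    def __post_init__(self):
        if not (0 <= self.min_delay <= self.initial_delay <= self.max_rt):
            raise ValueError("need 0 <= min_delay <= initial_delay <= max_rt")
        if self.step <= 0:
            raise ValueError("staircase step must be positive")


@dataclass
class SimConfig:
    """Behavioral simulation parameters.

    ``go_rt`` holds the ex-Gaussian (mu, sigma, tau) of go finish times in
    ms; ``ssrt_true`` the between-subject (mean, SD) of the true stopping
    latency; ``ssrt_trial_sd`` its trial-to-trial jitter.
    """
    n_subjects: int = 1
    trials_per_subject: int = 1120  # 10 blocks of 112 trials
    condition_proportions: tuple = (0.50, 0.25, 0.25)  # GO, STOP, AC-GO
    go_rt: tuple = (430.0, 60.0, 120.0)
    ssrt_true: tuple = (240.0, 35.0)
    ssrt_trial_sd: float = 20.0
    ac_slowing: float = 40.0
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)
    omission_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not np.isclose(sum(self.condition_proportions), 1.0):
            raise ValueError("condition proportions must sum to 1")
        if min(self.condition_proportions) < 0:
            raise ValueError("condition proportions must be nonnegative")
        if self.go_rt[0] < 0 or self.ssrt_true[0] < 0 or self.ac_slowing < 0:
            raise ValueError("delays and RTs must be nonnegative")
        if not 0 <= self.omission_rate < 1:
            raise ValueError("omission_rate must be in [0, 1)")


@dataclass
class VarCoupling:
    """Directed VAR coupling between two source blocks.

    Each source follows a stochastic AR(2) oscillator with pole radius
    ``ar_r`` at frequency ``ar_freq``; the ``link`` pair additionally couples
    with lag-1 coefficients ``coupling = (forward, backward)``, active only
    inside ``gate_window`` (ms after signal onset) of ``condition`` trials.
    """
    link: tuple = ("rIFG", "pre-SMA")
    coupling: tuple = (0.25, 0.0)
    ar_r: float = 0.90
    ar_freq: float = 32.0
    gate_window: tuple = (100.0, 350.0)
    condition: str = "sSTOP"
    scale: float = 0.7  # target SD of the VAR component in the signal


@dataclass
class BrainBehavior:
    """Linear ground-truth link from subject neural features to SSRT.

    Coefficients are in ms of SSRT per SD of the latent feature; the latent
    features modulate the recovery amplitude of the beta contrast (power
    regressors) and the VAR coupling asymmetry (DAI regressor).
    """
    coef: Mapping[str, float] = field(default_factory=lambda: {
        "rifg_s": -15.0, "rifg_f": 0.0,
        "presma_s": 0.0, "presma_f": 0.0, "dai": -10.0})
    noise_sd: float = 15.0
    dai_mean: float = 0.4
    dai_sd: float = 0.25
    base_coupling: float = 0.15  # symmetric VAR coupling the DAI modulates


@dataclass
class NeuralConfig:
    """Source-level epoch simulation parameters (times in ms, rates in Hz)."""
    sfreq: float = 400.0
    epoch_span: tuple = (-600.0, 1400.0)
    sources: Sequence[str] = DEFAULT_SOURCES
    n_components: int = 3
    mixing: tuple = (1.0, 0.3, 0.1)
    beta_band: tuple = (12.0, 32.0)
    desync_depth: float = 0.5
    desync_start: float = 100.0   # ms after GO
    desync_width: float = 150.0
    onset_rifg: float = 137.0     # ms after signal, sSTOP recovery at rIFG
    onset_lag: float = 22.0       # extra ms for pre-SMA
    onset_other_lag: float = 45.0  # extra ms for the remaining sources
    onset_subject_sd: float = 35.0
    rise_time: float = 50.0
    evoked_amp: float = 1.2
    evoked_freq: float = 22.0
    evoked_decay: float = 100.0
    broadband_noise: float = 0.5
    component_noise: float = 0.2
    var_coupling: VarCoupling | None = None
    brain_behavior: BrainBehavior | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.desync_depth <= 1.0:
            raise ValueError("desync_depth must be in [0, 1] so the "
                             "amplitude envelope stays nonnegative")
        if len(self.mixing) != self.n_components:
            raise ValueError("mixing weights must match n_components")
        if self.epoch_span[0] > -500.0:
            raise ValueError("epoch_span must cover a 500 ms pre-GO baseline")


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def _ex_gaussian(rng, mu, sigma, tau, size):
    return rng.normal(mu, sigma, size) + rng.exponential(tau, size)


def simulate_behavior(config: SimConfig,
                      ssrt_per_subject: np.ndarray | None = None
                      ) -> pd.DataFrame:
    """Simulate race-model behavior under the SSD staircase.

    Parameters
    ----------
    config : SimConfig
    ssrt_per_subject : array, optional
        Override the per-subject true SSRT means (used by the cohort
        generator to tie SSRT to neural ground truth).

    Returns
    -------
    DataFrame
        Trial table with columns (subject, trial, condition, direction,
        delay_ms, rt_ms, outcome).  ``attrs`` carry ``ssrt_true`` (per
        subject) and ``staircase_warning`` flags (delay pinned at a bound on
        more than half of the STOP trials).
    """
    rng = np.random.default_rng(config.seed)
    mu, sigma, tau = config.go_rt
    sc = config.staircase
    if ssrt_per_subject is None:
        ssrt_subj = config.ssrt_true[0] + config.ssrt_true[1] * \
            rng.standard_normal(config.n_subjects)
        ssrt_subj = np.maximum(ssrt_subj, 1.0)
    else:
        ssrt_subj = np.asarray(ssrt_per_subject, dtype=float)
        if ssrt_subj.size != config.n_subjects:
            raise ValueError("ssrt_per_subject length mismatch")

    rows = []
    warn_flags = {}
    for sub in range(config.n_subjects):
        conds = rng.choice(len(config.condition_proportions),
                           size=config.trials_per_subject,
                           p=config.condition_proportions)
        delay = sc.initial_delay
        n_stop = 0
        n_pinned = 0
        for t in range(config.trials_per_subject):
            cond = ("GO", "STOP", "AC-GO")[conds[t]]
            direction = "L" if rng.random() < 0.5 else "R"
            go_finish = _ex_gaussian(rng, mu, sigma, tau, None)
            omitted = rng.random() < config.omission_rate
            d = np.nan
            rt = np.nan
            if cond == "GO":
                if omitted or go_finish > sc.max_rt:
                    outcome = "omission"
                else:
                    rt = go_finish
                    outcome = "cGO"
            elif cond == "STOP":
                d = delay
                n_stop += 1
                if delay <= sc.min_delay or delay >= sc.max_rt:
                    n_pinned += 1
                stop_lat = max(0.0, rng.normal(ssrt_subj[sub],
                                               config.ssrt_trial_sd))
                responded = (not omitted and go_finish < d + stop_lat
                             and go_finish <= sc.max_rt)
                if responded:
                    rt = go_finish
                    outcome = "uSTOP"
                    delay = max(sc.min_delay, delay - sc.step)
                else:
                    outcome = "sSTOP"
                    delay = min(sc.max_rt, delay + sc.step)
            else:  # AC-GO follows the staircase trace without updating it
                d = delay
                if omitted:
                    outcome = "acOmission"
                else:
                    rt = go_finish if go_finish <= d \
                        else go_finish + config.ac_slowing
                    if rt > sc.max_rt:
                        rt = np.nan
                        outcome = "acOmission"
                    else:
                        outcome = "cAC-GO"
            rows.append((sub, t, cond, direction, d, rt, outcome))
        pinned_frac = n_pinned / max(n_stop, 1)
        warn_flags[sub] = bool(pinned_frac > 0.5)
        if warn_flags[sub]:
            warnings.warn(f"subject {sub}: staircase pinned at a bound on "
                          f"{100 * pinned_frac:.0f}% of STOP trials",
                          stacklevel=2)

    trials = pd.DataFrame(rows, columns=["subject", "trial", "condition",
                                         "direction", "delay_ms", "rt_ms",
                                         "outcome"])
    trials.attrs["ssrt_true"] = ssrt_subj
    trials.attrs["staircase_warning"] = warn_flags
    return validate_trials(trials)


# ---------------------------------------------------------------------------
# neural epochs
# ---------------------------------------------------------------------------

def _ramp(t, start, width):
    """Linear 0 -> 1 ramp beginning at ``start`` with duration ``width``."""
    if width <= 0:
        return (t >= start).astype(float)
    return np.clip((t - start) / width, 0.0, 1.0)


def _beta_carrier(rng, band, sfreq, shape):
    """Band-limited unit-variance Gaussian noise carrier."""
    lo, hi = band
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=sfreq, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _subject_onsets(rng, cfg: NeuralConfig):
    """Per-source recovery onsets (ms after signal) for one subject."""
    base = cfg.onset_rifg + cfg.onset_subject_sd * rng.standard_normal()
    base = max(base, 20.0)
    onsets = {}
    for s in cfg.sources:
        if s == "rIFG":
            onsets[s] = base
        elif s == "pre-SMA":
            onsets[s] = base + cfg.onset_lag
        else:
            onsets[s] = base + cfg.onset_lag + cfg.onset_other_lag
    return onsets


def _stable_var_or_raise(cfg: VarCoupling):
    """Reject unstable VAR coupling before simulating (companion check)."""
    a1 = 2 * cfg.ar_r * np.cos(2 * np.pi * cfg.ar_freq / 400.0)
    a2 = -cfg.ar_r ** 2
    c_fwd, c_bwd = cfg.coupling
    # two coupled AR(2) nodes -> companion matrix of the lag-2 system
    A1 = np.array([[a1, c_bwd], [c_fwd, a1]])
    A2 = np.diag([a2, a2])
    top = np.hstack([A1, A2])
    bottom = np.hstack([np.eye(2), np.zeros((2, 2))])
    comp = np.vstack([top, bottom])
    rad = np.max(np.abs(np.linalg.eigvals(comp)))
    if rad >= 1.0:
        raise ValueError(f"unstable VAR coupling (spectral radius {rad:.3f})")


def _simulate_var_block(rng, cfg: VarCoupling, sfreq, n_trials, n_samples,
                        gate_mask, scale_fwd=1.0, scale_bwd=1.0):
    """Two coupled AR(2) oscillators; coupling active where gate_mask is True.

    Returns array (n_trials, 2, n_samples) scaled to unit SD per channel.
    """
    a1 = 2 * cfg.ar_r * np.cos(2 * np.pi * cfg.ar_freq / sfreq)
    a2 = -cfg.ar_r ** 2
    c_fwd = cfg.coupling[0] * scale_fwd
    c_bwd = cfg.coupling[1] * scale_bwd
    innov = rng.standard_normal((n_trials, 2, n_samples))
    x = np.zeros((n_trials, 2, n_samples))
    for t in range(2, n_samples):
        g = gate_mask[:, t] if gate_mask.ndim == 2 else gate_mask[t]
        x[:, 0, t] = (a1 * x[:, 0, t - 1] + a2 * x[:, 0, t - 2]
                      + g * c_bwd * x[:, 1, t - 1] + innov[:, 0, t])
        x[:, 1, t] = (a1 * x[:, 1, t - 1] + a2 * x[:, 1, t - 2]
                      + g * c_fwd * x[:, 0, t - 1] + innov[:, 1, t])
    # normalize by the closed-form stationary SD of the uncoupled AR(2):
    # a data-dependent per-trial scale would couple out-of-gate samples to
    # the gate period and leak condition information outside the gate
    var0 = (1 - a2) / ((1 + a2) * ((1 - a2) ** 2 - a1 ** 2))
    return x / np.sqrt(var0)


def simulate_source_epochs(trials: pd.DataFrame, config: NeuralConfig,
                           recovery: Mapping | None = None) -> SourceEpochs:
    """Simulate source-level epochs for all signal-bearing trials.

    Only STOP and AC-GO trials carry a signal anchor and are simulated.
    ``recovery`` optionally maps subject -> {(source, 's'|'f'): fraction}
    scaling the post-onset beta recovery (and the evoked transient) per
    subject, region and trial success; the cohort generator uses it to
    inject brain-behavior effects.  Ground-truth onsets per subject and
    source are stored on the returned object as ``.ground_truth``.
    """
    validate_trials(trials)
    sig = trials[trials["condition"].isin(["STOP", "AC-GO"])].reset_index(drop=True)
    if len(sig) == 0:
        raise ValueError("no STOP or AC-GO trials to simulate")
    cfg = config
    t0, t1 = cfg.epoch_span
    max_delay = float(np.nanmax(sig["delay_ms"].to_numpy(dtype=float)))
    if t1 < max_delay + 700.0:
        raise ValueError(
            f"epoch_span end {t1} ms is too short: the largest signal delay "
            f"is {max_delay:.0f} ms and 700 ms post-signal must be covered; "
            f"need at least {max_delay + 700.0:.0f} ms")
    dt = 1000.0 / cfg.sfreq
    n_samples = int(round((t1 - t0) / dt)) + 1
    times = t0 + dt * np.arange(n_samples)

    rng = np.random.default_rng(cfg.seed)
    n_src = len(cfg.sources)
    mixing = np.asarray(cfg.mixing, dtype=float)

    data = np.empty((len(sig), n_src, cfg.n_components, n_samples))
    ground_truth = {"onsets": {}}

    if cfg.var_coupling is not None:
        _stable_var_or_raise(cfg.var_coupling)

    for sub in sorted(sig["subject"].unique()):
        sub_rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 1000003, int(sub)]))
        onsets = _subject_onsets(sub_rng, cfg)
        ground_truth["onsets"][sub] = onsets
        idx = np.flatnonzero((sig["subject"] == sub).to_numpy())
        nt = idx.size
        delays = sig["delay_ms"].to_numpy(dtype=float)[idx]
        rts = sig["rt_ms"].to_numpy(dtype=float)[idx]
        outcomes = sig["outcome"].to_numpy()[idx]
        rec = recovery.get(sub) if recovery is not None else None

        is_stop = np.isin(outcomes, ("sSTOP", "uSTOP"))
        down = _ramp(times, cfg.desync_start, cfg.desync_width)[None, :]
        sub_data = np.empty((nt, n_src, n_samples))
        for si, src in enumerate(cfg.sources):
            carrier = _beta_carrier(sub_rng, cfg.beta_band, cfg.sfreq,
                                    (nt, n_samples))
            # per-trial recovery time and fraction
            rho = np.ones(nt)
            t_rec = np.where(np.isnan(rts), delays + 600.0, rts)
            for k in np.flatnonzero(is_stop):
                key = "s" if outcomes[k] == "sSTOP" else "f"
                r = rec.get((src, key), 1.0) if rec is not None else 1.0
                if outcomes[k] == "uSTOP":
                    r *= 0.7  # failed stops recover less
                rho[k] = r
                t_rec[k] = delays[k] + onsets[src]
            if cfg.rise_time > 0:
                up = np.clip((times[None, :] - t_rec[:, None])
                             / cfg.rise_time, 0.0, 1.0)
            else:
                up = (times[None, :] >= t_rec[:, None]).astype(float)
            env = 1.0 - cfg.desync_depth * down * (1.0 - rho[:, None] * up)
            # phase-locked stop-evoked beta transient at the onset
            tt = (times[None, :] - t_rec[:, None]) / 1000.0
            act = (tt >= 0) & is_stop[:, None]
            evoked = np.where(
                act,
                (cfg.evoked_amp * cfg.desync_depth * rho[:, None]
                 * np.exp(-np.maximum(tt, 0.0) * 1000.0 / cfg.evoked_decay)
                 * np.sin(2 * np.pi * cfg.evoked_freq * tt)),
                0.0)
            sub_data[:, si] = (carrier * env + evoked
                               + cfg.broadband_noise
                               * sub_rng.standard_normal((nt, n_samples)))

        if cfg.var_coupling is not None:
            vc = cfg.var_coupling
            ia = list(cfg.sources).index(vc.link[0])
            ib = list(cfg.sources).index(vc.link[1])
            gate = np.zeros((nt, n_samples), dtype=bool)
            in_cond = outcomes == vc.condition
            lo = delays[:, None] + vc.gate_window[0]
            hi = delays[:, None] + vc.gate_window[1]
            gate = (times[None, :] >= lo) & (times[None, :] <= hi) \
                & in_cond[:, None]
            s_fwd = s_bwd = 1.0
            if rec is not None and "coupling_scale" in rec:
                s_fwd, s_bwd = rec["coupling_scale"]
            block = _simulate_var_block(sub_rng, vc, cfg.sfreq, nt, n_samples,
                                        gate, s_fwd, s_bwd)
            sub_data[:, ia] += vc.scale * block[:, 0]
            sub_data[:, ib] += vc.scale * block[:, 1]

        comps = (mixing[None, None, :, None] * sub_data[:, :, None, :]
                 + cfg.component_noise
                 * sub_rng.standard_normal((nt, n_src, cfg.n_components,
                                            n_samples)))
        data[idx] = comps

    epochs = SourceEpochs(data=data, times=times, sfreq=cfg.sfreq,
                          sources=list(cfg.sources), trials=sig)
    epochs.ground_truth = ground_truth
    return epochs


# ---------------------------------------------------------------------------
# cohort generator with brain-behavior ground truth
# ---------------------------------------------------------------------------

def simulate_var_cohort(config: SimConfig, neural: NeuralConfig):
    """Simulate a cohort with known connectivity and brain-behavior links.

    Per subject, latent z-scored features (beta recovery strength in rIFG and
    pre-SMA for successful and failed stops, and the directed-coupling
    asymmetry) are drawn first; the subject's true SSRT is their configured
    linear combination plus noise, and the neural generator scales the
    envelope recovery and the VAR coupling so that the analysis chain can
    re-estimate the injected quantities.

    Returns
    -------
    (trials, epochs, ground_truth)
        ``ground_truth`` maps each injected parameter (latents per subject,
        true SSRTs, DAI, onsets, coefficients) by name.
    """
    if neural.var_coupling is None or neural.brain_behavior is None:
        raise ValueError("simulate_var_cohort needs var_coupling and "
                         "brain_behavior configured")
    bb = neural.brain_behavior
    # symmetric base coupling; per-subject asymmetry injects the DAI
    from dataclasses import replace as _replace
    neural = _replace(neural, var_coupling=_replace(
        neural.var_coupling,
        coupling=(bb.base_coupling, bb.base_coupling)))
    rng = np.random.default_rng(np.random.SeedSequence([neural.seed, 77]))
    n = config.n_subjects
    latents = {k: rng.standard_normal(n)
               for k in ("rifg_s", "rifg_f", "presma_s", "presma_f", "dai")}
    dai_true = np.clip(bb.dai_mean + bb.dai_sd * latents["dai"], -0.95, 0.95)
    ssrt_true = (config.ssrt_true[0]
                 + sum(bb.coef[k] * latents[k] for k in latents)
                 + bb.noise_sd * rng.standard_normal(n))
    ssrt_true = np.maximum(ssrt_true, 60.0)

    trials = simulate_behavior(config, ssrt_per_subject=ssrt_true)

    # latent -> multiplicative recovery fraction, kept inside (0.05, 1.6)
    def frac(z):
        return float(np.clip(0.8 + 0.3 * z, 0.05, 1.6))

    recovery = {}
    for sub in range(n):
        # coupling asymmetry: GC scales roughly with the squared coefficient
        c_fwd = np.sqrt((1.0 + dai_true[sub]) / 2.0)
        c_bwd = np.sqrt((1.0 - dai_true[sub]) / 2.0)
        recovery[sub] = {
            ("rIFG", "s"): frac(latents["rifg_s"][sub]),
            ("rIFG", "f"): frac(latents["rifg_f"][sub]),
            ("pre-SMA", "s"): frac(latents["presma_s"][sub]),
            ("pre-SMA", "f"): frac(latents["presma_f"][sub]),
            "coupling_scale": (c_fwd, c_bwd),
        }

    epochs = simulate_source_epochs(trials, neural, recovery=recovery)
    ground_truth = {
        "latents": latents,
        "dai_true": dai_true,
        "ssrt_true": ssrt_true,
        "coef": dict(bb.coef),
        "onsets": epochs.ground_truth["onsets"],
        "recovery": recovery,
    }
    return trials, epochs, ground_truth
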