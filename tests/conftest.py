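import warnings

import numpy as np
import pandas as pd
import pytest

from stopbeta.containers import SourceEpochs
from stopbeta.synthetic import NeuralConfig, SimConfig, simulate_behavior, \
    simulate_source_epochs

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def behavior_table():
    """Two simulated subjects under default task conditions."""
    cfg = SimConfig(n_subjects=2, trials_per_subject=800, seed=42)
    return simulate_behavior(cfg)


@pytest.fixture(scope="session")
def two_source_epochs():
    """One subject's rIFG / pre-SMA epochs with fixed ground-truth onsets."""
    cfg = SimConfig(n_subjects=1, trials_per_subject=1120, seed=42)
    trials = simulate_behavior(cfg)
    ncfg = NeuralConfig(seed=42, sources=("rIFG", "pre-SMA"),
                        onset_subject_sd=0.0)
    return trials, simulate_source_epochs(trials, ncfg)


def make_epochs(data, sfreq=400.0, t0=-600.0, sources=None, delays=200.0,
                outcome="sSTOP", rts=np.nan):
    """Hand-built SourceEpochs around an array (trials, src, comp, samples)."""
    data = np.asarray(data, dtype=float)
    nt, ns = data.shape[:2]
    times = t0 + 1000.0 / sfreq * np.arange(data.shape[-1])
    sources = sources or [f"s{i}" for i in range(ns)]
    delays = np.broadcast_to(np.asarray(delays, dtype=float), nt)
    outcome = np.broadcast_to(np.asarray(outcome), nt)
    rts = np.broadcast_to(np.asarray(rts, dtype=float), nt)
    cond = np.where(np.isin(outcome, ("cAC-GO", "acOmission")), "AC-GO",
                    np.where(np.isin(outcome, ("sSTOP", "uSTOP")), "STOP",
                             "GO"))
    trials = pd.DataFrame({
        "subject": 0, "trial": np.arange(nt), "condition": cond,
        "direction": "L", "delay_ms": delays, "rt_ms": rts,
        "outcome": outcome})
    return SourceEpochs(data=data, times=times, sfreq=sfreq,
                        sources=list(sources), trials=trials)
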