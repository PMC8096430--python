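"""Core data containers: behavioral trial tables and source-level epochs.

The behavioral observable is a *trial table*, one row per trial, carried as a
:class:`pandas.DataFrame` with a fixed column set.  Neural data are
*source-level epochs*: an array of shape ``(trials, sources, components,
samples)`` holding reconstructed virtual-channel time courses with a few dipole
components per source.  Epochs carry two event anchors per trial: the GO cue
(the common time origin of the sample grid) and the STOP/AC-GO signal, whose
latency varies trial by trial with the staircased delay.  Baseline windows are
GO-locked while task windows are signal-locked, so the container supports both
alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

#: canonical trial-table columns (TSV order)
TRIAL_COLUMNS = ["subject", "trial", "condition", "direction",
                 "delay_ms", "rt_ms", "outcome"]

CONDITIONS = ("GO", "STOP", "AC-GO")
OUTCOMES = ("cGO", "omission", "sSTOP", "uSTOP", "cAC-GO", "acOmission")


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Check trial-table structure and outcome/condition consistency."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    bad_cond = set(trials["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(f"unknown conditions: {bad_cond}")
    bad_out = set(trials["outcome"]) - set(OUTCOMES)
    if bad_out:
        raise ValueError(f"unknown outcomes: {bad_out}")
    # sSTOP implies no button press; uSTOP implies a press
    sstop = trials["outcome"] == "sSTOP"
    if trials.loc[sstop, "rt_ms"].notna().any():
        raise ValueError("sSTOP trials must not carry an RT")
    ustop = trials["outcome"] == "uSTOP"
    if trials.loc[ustop, "rt_ms"].isna().any():
        raise ValueError("uSTOP trials must carry an RT")
    return trials


def read_trials(path) -> pd.DataFrame:
    """Read a trial table from TSV."""
    return validate_trials(pd.read_csv(path, sep="\t"))


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table to TSV (canonical column order)."""
    trials[TRIAL_COLUMNS].to_csv(path, sep="\t", index=False)


@dataclass
class SourceEpochs:
    """Source-level epochs with dual (GO / signal) time anchors.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_sources, n_components, n_samples)
        Virtual-channel time courses.
    times : ndarray, shape (n_samples,)
        Sample times in ms relative to GO onset.
    sfreq : float
        Sampling rate in Hz.
    sources : sequence of str
        Ordered source labels.
    trials : DataFrame
        Per-epoch rows of the behavioral trial table (``delay_ms`` gives the
        signal anchor relative to GO onset).
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    sources: Sequence[str]
    trials: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("data must be (trials, sources, components, samples)")
        if self.data.shape[0] != len(self.trials):
            raise ValueError("trials table does not match data")
        if self.data.shape[1] != len(self.sources):
            raise ValueError("source labels do not match data")
        if self.data.shape[3] != self.times.size:
            raise ValueError("times do not match data")
        self.trials = self.trials.reset_index(drop=True)

    # -- basic structure -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        return self.data.shape[2]

    def source_index(self, label: str) -> int:
        try:
            return list(self.sources).index(label)
        except ValueError:
            raise KeyError(f"unknown source {label!r}; have {list(self.sources)}")

    def select(self, mask) -> "SourceEpochs":
        """Subset trials by boolean mask or integer indices."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return replace(self, data=self.data[idx],
                       trials=self.trials.iloc[idx].reset_index(drop=True))

    def select_outcome(self, *outcomes: str) -> "SourceEpochs":
        return self.select(self.trials["outcome"].isin(outcomes).to_numpy())

    def select_sources(self, labels: Sequence[str]) -> "SourceEpochs":
        """Restrict to the given sources, in the given order."""
        idx = [self.source_index(s) for s in labels]
        return replace(self, data=self.data[:, idx], sources=list(labels))

    # -- alignment -------------------------------------------------------
    def go_locked(self, tmin: float, tmax: float):
        """Crop to a GO-locked window [tmin, tmax] ms; returns (data, times)."""
        sel = (self.times >= tmin - 1e-9) & (self.times <= tmax + 1e-9)
        if not sel.any():
            raise ValueError(f"window {tmin}..{tmax} ms outside epoch span "
                             f"{self.times[0]}..{self.times[-1]} ms")
        return self.data[..., sel], self.times[sel]

    def signal_locked(self, tmin: float, tmax: float):
        """Re-align trials to the STOP/AC-GO signal onset.

        Returns ``(data, times)`` where ``times`` run from ``tmin`` to
        ``tmax`` ms relative to the signal and ``data`` has the same leading
        axes as :attr:`data`.  Trials without a defined delay (plain GO
        trials) cannot be signal-locked.
        """
        delays = self.trials["delay_ms"].to_numpy(dtype=float)
        if np.isnan(delays).any():
            raise ValueError("cannot signal-lock trials without a signal delay")
        dt = 1000.0 / self.sfreq
        n_win = int(round((tmax - tmin) / dt)) + 1
        out_times = tmin + dt * np.arange(n_win)
        t0 = self.times[0]
        start = np.round((delays + tmin - t0) / dt).astype(int)
        if start.min() < 0 or (start.max() + n_win) > self.times.size:
            raise ValueError(
                f"signal-locked window {tmin}..{tmax} ms does not fit the "
                f"epoch span {self.times[0]}..{self.times[-1]} ms (GO-locked) "
                f"for delays {delays.min()}..{delays.max()} ms; "
                "extend epoch_span")
        idx = start[:, None] + np.arange(n_win)[None, :]
        out = np.take_along_axis(self.data, idx[:, None, None, :], axis=3)
        return out, out_times

    # -- I/O ---------------------------------------------------------------
    def to_hdf5(self, path, mode: str = "a") -> None:
        """Write epochs to HDF5 under ``/subject_<id>/``.

        Layout: dataset ``data`` (trials x sources x components x samples),
        dataset ``times`` (ms, GO-locked), dataset ``signal_onset_ms`` (per
        trial), attrs ``sampling_rate`` and ``source_labels``, plus the trial
        table columns as datasets under ``trials/``.
        """
        subjects = self.trials["subject"].unique()
        with h5py.File(path, mode) as f:
            for sub in subjects:
                mask = (self.trials["subject"] == sub).to_numpy()
                ep = self.select(mask)
                g = f.create_group(f"subject_{sub}")
                g.create_dataset("data", data=ep.data)
                g.create_dataset("times", data=ep.times)
                g.create_dataset(
                    "signal_onset_ms",
                    data=ep.trials["delay_ms"].to_numpy(dtype=float))
                g.attrs["sampling_rate"] = self.sfreq
                g.attrs["source_labels"] = [str(s) for s in self.sources]
                tg = g.create_group("trials")
                for col in TRIAL_COLUMNS:
                    vals = ep.trials[col].to_numpy()
                    if vals.dtype == object:
                        vals = vals.astype("S")
                    tg.create_dataset(col, data=vals)

    @classmethod
    def from_hdf5(cls, path, subject=None) -> "SourceEpochs":
        """Read epochs for one subject (or the only subject) from HDF5."""
        with h5py.File(path, "r") as f:
            keys = sorted(k for k in f if k.startswith("subject_"))
            if subject is not None:
                key = f"subject_{subject}"
            elif len(keys) == 1:
                key = keys[0]
            else:
                raise ValueError(f"file holds several subjects {keys}; "
                                 "pass subject=")
            g = f[key]
            cols = {}
            for col in TRIAL_COLUMNS:
                vals = g["trials"][col][()]
                if vals.dtype.kind == "S":
                    vals = vals.astype(str)
                cols[col] = vals
            trials = pd.DataFrame(cols)
            return cls(data=g["data"][()], times=g["times"][()],
                       sfreq=float(g.attrs["sampling_rate"]),
                       sources=list(g.attrs["source_labels"]),
                       trials=trials)

    def concat(self, other: "SourceEpochs") -> "SourceEpochs":
        """Stack trials of two epoch sets on identical grids."""
        if not np.allclose(self.times, other.times) or self.sfreq != other.sfreq:
            raise ValueError("epoch grids differ")
        if list(self.sources) != list(other.sources):
            raise ValueError("source sets differ")
        return replace(self, data=np.concatenate([self.data, other.data]),
                       trials=pd.concat([self.trials, other.trials],
                                        ignore_index=True))
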