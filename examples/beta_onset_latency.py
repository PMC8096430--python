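"""Beta-band desynchronization-termination onsets: rIFG before pre-SMA.

Simulates a small cohort whose successful-stop trials carry a beta-power
recovery starting 22 ms earlier in rIFG than in pre-SMA, runs the
time-frequency contrast chain (baseline z-scoring, beta-band averaging,
fractional-threshold onset detection) and tests the group-level onset
difference with a paired permutation test.
"""

import numpy as np

from stopbeta import NeuralConfig, SimConfig, simulate_behavior, \
    simulate_source_epochs
from stopbeta.latency import onset_permutation_test
from stopbeta.pipeline import select_ac_epochs, subject_onsets
from stopbeta.spectral import AnalysisParams, principal_component_reduce

N_SUBJECTS = 12
params = AnalysisParams()
onsets = {"rIFG": [], "pre-SMA": []}
for s in range(N_SUBJECTS):
    trials = simulate_behavior(SimConfig(n_subjects=1,
                                         trials_per_subject=1120, seed=s))
    epochs = simulate_source_epochs(
        trials, NeuralConfig(seed=s, sources=("rIFG", "pre-SMA")))
    epochs = principal_component_reduce(select_ac_epochs(epochs, 244.0), 1)
    est = subject_onsets(epochs, params)
    if not any(e.excluded for e in est.values()):
        for src in onsets:
            onsets[src].append(est[src].onset_ms)

a, b = np.array(onsets["rIFG"]), np.array(onsets["pre-SMA"])
p, mean_r, mean_p = onset_permutation_test(a, b, n_perm=50_000, seed=0)
print(f"subjects with defined onsets: {a.size}/{N_SUBJECTS}")
print(f"mean onset rIFG    {mean_r:.0f} ms (SD {a.std():.0f})")
print(f"mean onset pre-SMA {mean_p:.0f} ms (SD {b.std():.0f})")
print(f"onset lag          {mean_p - mean_r:.1f} ms (injected 22 ms)")
print(f"permutation p      {p:.4f}  (50,000 permutations, two-tailed)")

# The recovered lag approximates the injected 22 ms rIFG lead; with only 12
# subjects the permutation p fluctuates around the detection threshold.
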