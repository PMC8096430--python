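# stopbeta

Analysis chain for stop-signal MEG studies of motor inhibition: behavioral
SSRT estimation, beta-band time-frequency contrasts with onset-latency
statistics, time-resolved decoding, nonparametric conditional Granger
causality with the directed influence asymmetry index (DAI), and Bayesian
regression of stopping performance — together with a synthetic-data
generator that produces cohorts with known ground truth so that every stage
can be validated end to end without access to recordings.

## The scientific problem

In the stop-signal task a prepared go response must occasionally be
cancelled after a delayed stop signal.  Under the independent horse-race
model a response is emitted iff the go process finishes before the stop
process: the latent stop latency (SSRT) is estimated with the *integration
method* — with p = p(respond|signal) observed under a 1-up/1-down staircase
of the stop-signal delay (SSD), the SSRT is the RT at rank
`round(N_GO * p)` of the ascending go-RT distribution minus the mean SSD.

Which cortical area *initiates* stopping is contested between the right
inferior frontal gyrus (rIFG) and the pre-supplementary motor area
(pre-SMA).  The package implements the full source-level evidence chain for
this question on epochs of reconstructed virtual-channel activity:

- **Latency.** Beta-band (12–32 Hz) power of successful-stop trials is
  contrasted against attentional-capture go trials (z-scored against a
  GO-locked baseline); the onset at which the contrast first rises (25% of
  the range between the first positive peak in the 100–350 ms tROI and the
  clamped pre-peak minimum) is compared between rIFG and pre-SMA with a
  paired permutation test.
- **Decoding.** A time-resolved linear max-margin classifier on
  supertrial-averaged, 14-sample time-embedded source signals provides an
  independent, frequency-agnostic onset estimate of condition
  discriminability.
- **Connectivity.** Cross-spectral densities over the tROI are factorized
  with Wilson's algorithm (S = H Σ H*) and combined Geweke-style into
  frequency-resolved conditional Granger causality between 2-PC source
  blocks, with trial-shuffle bias thresholds, cluster-based condition
  contrasts, and `DAI = (GC(A→B) − GC(B→A)) / (GC(A→B) + GC(B→A))`.
- **Brain–behavior.** Per-subject SSRT is regressed on beta-power
  contrasts and the DAI under Normal(0, 0.5) coefficient priors and a
  half-Normal(1) noise prior; model variants are compared with PSIS-LOO.

## Worked example

```sh
python examples/behavior_ssrt.py
```

```
trials simulated:        1120
p(respond | stop signal) 0.500
mean SSD                 209.2 ms
mean RT  cGO / uSTOP / cAC-GO: 540 / 457 / 585 ms
estimated SSRT           312.5 ms (true 311.4 ms)
exclusion flags          none
```

The staircase holds stopping success at 50%; unsuccessful-stop responses
come from the fast tail of the go distribution (uSTOP < cGO < cAC-GO mean
RTs, the race-model signature); and the integration-method estimate
recovers the generator's true stopping latency to ~1 ms here.

The other example scripts exercise one capability each:
`beta_onset_latency.py` (TFR onset lag, rIFG before pre-SMA),
`decoding_onsets.py` (time-resolved classification onsets),
`connectivity_dai.py` (conditional GC, bias threshold, DAI),
`bayesian_regression.py` (model comparison and sign probabilities).

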