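# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the known limitations of the `stopbeta` analysis
chain.

## Behavioral model and SSRT

Go finish times are ex-Gaussian, `mu + sigma*N(0,1) + Exp(tau)` with
defaults (430, 60, 120) ms, giving the right-skewed RT distributions and a
~550 ms mean go RT typical of selective stopping tasks.  The stop process
is a per-trial Gaussian latency around the subject's true SSRT, truncated
at zero (`ssrt_trial_sd`, default 20 ms).  On STOP trials a response is
emitted iff the go process finishes before SSD + stop latency; the SSD then
steps −30 ms after an unsuccessful stop and +30 ms after a successful one
(initial 210 ms, floor 40 ms, ceiling at the 1000 ms response deadline).
AC-GO (attentional-capture go) trials read the current staircase delay
without updating it, and their responses are the go response plus a 40 ms
attentional-capture slowing; omissions are injected at 2%.  A staircase
pinned at a bound on more than half of the STOP trials raises a warning
and flags the subject.

The integration-method SSRT sorts all go-condition RTs ascending (omissions
replaced by the maximum RT), takes the RT at rank `round(N_GO *
p_respond)` (round-half-up, clamped to [1, N_GO]) and subtracts the mean
SSD over all STOP trials.  Under the adaptive staircase the estimator is
within ±15 ms of the generating SSRT at large trial counts when the stop
latency is fixed; trial-to-trial latency jitter adds a small downward bias
(≤ 10 ms at the default 20 ms jitter), which the tests account for with a
±25 ms band.  Subjects are flagged when p(respond|signal) < 0.40 or when
the mean uSTOP RT exceeds the mean cGO RT (race-model violation).

## Synthetic source epochs

Each source emits a band-limited beta carrier (12–32 Hz Butterworth-filtered
Gaussian noise, unit SD) multiplied by an amplitude envelope: flat baseline;
a linear desynchronization ramp starting 100 ms after the GO cue (width
150 ms, depth 0.5); and a linear recovery ramp (rise time 50 ms) that
begins, in successful-stop trials, at the source's characteristic onset
after the signal — rIFG first, pre-SMA 22 ms later, remaining sources later
still.  In correct AC-GO trials the desynchronization persists until the
button press; unsuccessful stops recover partially (×0.7).  A phase-locked
22 Hz evoked transient (exponential decay 100 ms) with the same onset
carries the condition difference into the time domain for the decoding
route.  Sources are expanded to three dipole components with mixing weights
(1.0, 0.3, 0.1) plus component noise, so principal-component reduction is
well-posed, and broadband white noise (SD 0.5) is added.  Epochs store the
GO-locked sample grid plus the per-trial signal delay, because baselines
are GO-locked while analysis windows are signal-locked.

Free amplitude parameters were calibrated once, during development,
against the observable statistics such cohorts are expected to show:
1120 trials per subject (ten 112-trial blocks); a desynchronization depth
and between-subject onset jitter (SD 35 ms) that reproduce per-source
onset dispersions of roughly ±40–50 ms in the TFR latency route; and an
evoked amplitude (1.2 × depth × recovery fraction) at which the decoding
route classifies robustly at the group level while its single-cohort
latency contrast has the marginal strength (t ≈ 2) empirically reported
for that analysis.  These calibrated values are the frozen study
conditions of all recovery tests.

For connectivity and brain–behavior studies, `simulate_var_cohort` draws
per-subject latent features (beta recovery strength per region and trial
type; a coupling-asymmetry latent mapped to the DAI), builds the true SSRT
as a configured linear combination (defaults: −15 ms/SD for the rIFG
successful-stop contrast, −10 ms/SD for the DAI, residual SD 15 ms), and
scales the envelope recovery and a condition-gated VAR coupling
accordingly.  The VAR component adds two AR(2) oscillators (pole radius
0.9 at 32 Hz) at rIFG and pre-SMA with symmetric base coupling 0.15 whose
forward/backward split `sqrt((1±DAI)/2)` injects the asymmetry; coupling
is active only inside the 100–350 ms window of sSTOP trials.  Stability is
verified via the companion-matrix spectral radius before simulation.

What the generator does **not** emulate: sensor-space mixing and source
leakage, non-stationary noise and artifacts, burst-like (non-Gaussian)
beta amplitude dynamics, evoked fields in the control condition, and any
subcortical contribution.  Passing recovery tests therefore demonstrate
the correctness and calibration of the analysis chain, not the physiology
of real recordings.

## Spectral analysis

Analysis windows are extended to an integer number of cycles of the band
center frequency (100–350 ms → 100–373 ms at 22 Hz).  Multitaper spectra
use discrete prolate spheroidal tapers with `floor(2*T*W) − 1` tapers —
four for the beta band (T = 273 ms, half-bandwidth 10 Hz), five for the
gamma band (12 Hz).  PSD scaling is one-sided with unit-energy tapers so
band-integrated power matches time-domain variance (verified to within
10%).  TFRs use a sliding Hanning window of 3 cycles per frequency
(8–44 Hz in 2 Hz steps, 10 ms time grid); edge samples with incomplete
windows are NaN.  Condition TFRs are z-scored by subtracting each
condition's own baseline mean and dividing by the SD over the pooled
baseline trials, per frequency; the baseline is the window of tROI length
ending 100 ms before the GO cue.  Per source, dipole components are
reduced by eigen-decomposition of the component covariance pooled over
trials and samples (dominant orientation first; deterministic sign fix).

## Cluster permutation statistics

Paired condition contrasts are tested with the cluster mass statistic:
samples with |t| above the paired-t quantile at the cluster-forming alpha
form clusters under the grid adjacency (contiguous runs in 1-D,
4-connectivity in 2-D, or a user adjacency callback); the null distribution
is the maximum |cluster mass| over within-subject condition swaps (sign
flips of difference maps), so family-wise error is controlled by the
max-statistic convention.  p-values use the (1 + count)/(n_perm + 1)
estimator.  Because the sign-flip null rescales together with the effect,
the deterministic monotone quantity under effect scaling is the observed
cluster mass, not the p-value; the tests check mass monotonicity plus
sustained significance.  Null calibration: family-wise false-positive rate
within two binomial SEs of alpha over 200 replicate null cohorts.

## Onset latency

The beta-band contrast series z(sSTOP) − z(cAC-GO) is averaged over
12–32 Hz and smoothed with a centered moving average before onset
detection.  The onset is the first time the series exceeds
`min + fraction*(peak − min)`, where the peak is the first positive local
maximum inside the 100–350 ms tROI (plateaus take their earliest sample)
and the pre-peak minimum, searched from 0 ms, is clamped at zero.  Subjects
without a positive tROI peak are flagged and excluded from the group
permutation test on mean paired onset differences.

The smoothing default is 90 ms (matched to the ~±68 ms temporal support of
the 3-cycle Hanning window at the beta center frequency), not a smaller
value: with light smoothing, noise wiggles on the smeared foot of the
power rise create spurious "first positive peaks", which pulls late onsets
early, compresses injected latency differences (a 22 ms lag shrank to
~13 ms) and destroys the rank order the group test depends on.  With the
matched kernel the recovered lag is 15–21 ms and the group test detects it
in ~7/8 replicate 50-subject cohorts.

## Time-resolved decoding

Source signals are z-scored per trial against the 500 ms pre-GO baseline,
optionally band-pass filtered (one-pass Butterworth, beta-specificity
variant), smoothed with a ±10 ms Gaussian kernel, resampled to 300 Hz and
causally embedded with 14 consecutive samples (one 22 Hz cycle) per time
point.  Per iteration, each condition's trials are randomly averaged into
eight supertrials; a linear max-margin classifier (L1-hinge SVM, C = 1) is
trained at every time point with one held-out supertrial per condition,
rotating over all eight folds; accuracy averages folds and iterations.
Trial counts are equalized across conditions before partitioning — with
unequal counts the two classes' supertrials carry different noise levels,
which a margin-based boundary converts into a systematic accuracy bias
even without any class signal.  The default solver is a batched dual
coordinate-descent implementation of the same optimization problem
liblinear solves (all time points and folds in one vectorized fit;
single-precision internally); `classifier="sklearn"` switches to
scikit-learn's `LinearSVC`, which also serves as the equivalence oracle in
the tests.

Group-level significance uses a one-sample cluster permutation test of
accuracy against the 50% chance level over tROI time points, with a
1000-resample bootstrap CI of the mean.  Individual onsets come from the
10 Hz zero-phase low-passed accuracy: the peak is the first tROI local
maximum above baseline mean + k·SD (k ∈ {1, 2}; fallback: the median time
of tROI points above the series' 95th percentile), and the onset is found
by walking backward from the peak to the earliest contiguous point above
baseline mean + fraction·(peak − baseline mean).

## Conditional Granger causality

CSD matrices over the tROI (5 Hz multitaper smoothing, zero-padded to a
256-point grid at 400 Hz) are factorized with Wilson's iterative spectral
matrix factorization into a minimum-phase transfer function and innovation
covariance.  Iteration stops when the relative step change falls below
1e-9 or stalls (the iteration enters a limit cycle on noisy CSDs);
convergence is then judged by the relative reconstruction error of
H Σ H* against the input CSD (must be < 1e-3).  Near-singular CSDs receive
diagonal loading of 1e-8 × the mean diagonal power.

Conditional GC from block X to block Y given blocks Z (each source block =
its first two principal components) follows Geweke's construction: the
reduced set {Y, Z} is factorized and embedded with identity on X; the full
factorization is rotated so the target-block innovations are uncorrelated
with all others; and
`f(λ) = ln det(Σ_R,yy) − ln det(Q_yy(λ) Σ_yy Q_yy(λ)*)` with
`Q = G_emb⁻¹ H̃`.  With no conditioning blocks this reduces exactly to
pairwise Geweke GC.  Validation: agreement with the closed-form parametric
GC of the generating VAR within 10% at the coupled-band peak (long
stationary segments, 1000 trials, narrow smoothing — wider multitaper
smoothing biases sharp GC peaks downward, which is why the oracle test
uses 1 Hz half-bandwidth while the study window uses the 5 Hz protocol
value), and the common-driver topology where conditioning removes the
spurious pairwise link.

GC estimation bias scales with the inverse trial count, so condition
contrasts are only interpretable on (approximately) count-matched trial
sets — the AC-GO selection rule produces this match in the standard chain,
and the temporal-specificity tests subsample explicitly.  Estimation bias
is measured by shuffling the trial correspondence of the
source block relative to the target and conditioning blocks: autospectra
are preserved exactly while cross-source covariance is destroyed.  The
reduced-model factorization is unaffected by the shuffle and is reused
across surrogates.  A link is significant when its 8–44 Hz mean exceeds
the 97.5th surrogate percentile.  Group condition contrasts run the 1-D
frequency cluster test over 8–44 Hz (cluster-forming p < 0.05) on subjects
with at least one significant condition link, at critical alpha 0.025 with
Bonferroni correction over the two directed links; sliding-window
contrasts repeat this for six 250 ms windows in 100 ms steps around the
tROI with Bonferroni ×12.  The DAI, `(GC_ab − GC_ba)/(GC_ab + GC_ba)`, is
evaluated at 30–40 Hz in 2 Hz steps and correlated with SSRT per frequency
(Pearson, 1000-resample bootstrap CIs at 99.17%, the Bonferroni level for
six frequencies).

## Bayesian regression

Regressors (beta-power contrast peaks for rIFG/pre-SMA × successful/failed
stops, and the DAI) and the SSRT outcome are z-normalized after exclusion
screening (positive contrast peak required in both regions and trial
types; |z| > 3 outliers dropped, then re-standardized).  Coefficients have
Normal(0, 0.5) priors; the residual SD a half-Normal(1) prior; no
intercept is fitted (all variables are centered).  Because the model is
linear-Gaussian, the posterior is drawn exactly by Gibbs sampling: the
coefficient block from its conjugate multivariate-Normal full conditional,
the noise SD by inverse-CDF on a 4000-point grid of its one-dimensional
full conditional.  Defaults keep 20,000 draws after 2,000 warm-up sweeps;
the effective sample size is close to the nominal draw count (the sampler
mixes almost independently), posterior means match the fixed-σ conjugate
closed form, and prior-only sampling reproduces the priors.  Model 1 adds
all ten first-order interaction products of the z-scored main effects
(not re-standardized); model 3 averages the two highly correlated pre-SMA
regressors.  elpd_loo uses PSIS (arviz) with exact leave-one-out refits
for observations whose Pareto-k exceeds 0.7; rankings report standard
errors and within-one-SE ties.

## Problem sizes used by the test suite

Unit tests run on purpose-built small fixtures.  The recovery suites use:
three replicate 50-subject cohorts per onset route (decoding with 15
supertrial iterations); one 50-subject cohort with three sources for
connectivity and regression recovery (60 bias surrogates per link and
condition, 5000 contrast permutations); 200 null replicates for cluster
calibration; and 1000 trials/tables for the GC and SSRT oracle checks.
Module defaults keep the study-protocol values (e.g. 1000 bias surrogates,
50,000 onset and contrast permutations, 100 decoding iterations).

## Known limitations

- The decoding-onset group contrast has intrinsically marginal power at
  the calibrated effect size (single-cohort t ≈ 2): across replicate
  cohorts it detects the injected 22 ms lag in roughly 60% of runs, versus
  ~85–90% for the TFR route.
- The integration-method SSRT inherits its known downward bias under stop-
  latency variability.
- Onset estimates carry the temporal smearing of the 3-cycle TFR window;
  absolute onsets are interpretable only relative to a common convention,
  while differences between sources are unbiased once the contrast series
  rises monotonically through its foot (hence the matched smoothing
  kernel).
- The Wilson factorization inherits multitaper smoothing bias: sharp GC
  spectral peaks are underestimated at the 5 Hz protocol smoothing.
- `gc_bias_threshold` at protocol settings (1000 surrogates) costs ~20 s
  per link/condition/subject on one core; cohort screenings in the tests
  reduce the surrogate count accordingly.
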