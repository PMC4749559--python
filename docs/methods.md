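# Methods

## The scientific question

In pulsatile evidence-accumulation tasks a subject watches two streams of
brief pulses (LED flashes left and right, or click trains in the auditory
variant) and reports which side delivered more. Behavioral variability in
such tasks is usually attributed to diffusion-like noise: independent
noise per pulse, so the standard deviation of the accumulated estimate
grows as the square root of the pulse count ("linear variance", LV). The
competing hypothesis from numerical cognition is scalar variability (SV):
the standard deviation of a count estimate grows *linearly* with the
count, as it does in interval timing and counting. A third is subitizing
(SUB): exact, noiseless representation of small counts (up to 3-4) with
scalar variability beyond. These laws make different predictions for how
errors depend on the total number of pulses at a fixed count difference,
and for whether performance depends on trial duration at all. This
package implements the full analysis chain that separates them, driven
entirely by a synthetic-data generator because no behavioral data are
distributed with it.

## Stimulus model

The generator emulates the visual task's statistics:

* The cue period is a sequence of 250-ms bins; each trial's bin count is
  drawn uniformly from 2-15 (freely-moving preset) or 2-6 (head-fixed
  preset), reproducing the trial-by-trial variation of stimulus duration
  that the task uses. Varying duration is load-bearing: it spreads the
  total pulse count over its full range, which is what lets the noise
  laws and the accumulator variants be told apart, and it supplies the
  duration variation the time-vs-count regressions need.
* One side per trial is designated high-probability (uniformly at
  random, recorded in the table); per bin the high side flashes with
  probability drawn once per trial from 70-80% and the low side from
  20-30% (fixed 70%/30% in the head-fixed and reverse-correlation
  presets). Flashes are 10 ms long and occupy the first 10 ms of their
  bin, so same-side inter-flash gaps are 240 ms (adjacent bins) up to
  (n_bins-1) x 250 - 10 ms: 1.24 s for the 6-bin geometry and 3.49 s for
  15 bins. (The 15-bin extreme follows from the stated bin geometry; we
  use the geometric rule throughout.)
* Reward goes to the side with more *actual* flashes; equal-count trials
  are rewarded uniformly at random and kept (they carry the
  duration-vs-number dissociation).
* The post-cue delay is uniform on 5-500 ms.
* The jitter variant draws flash durations from N(10, 1.5) ms (resampled
  until positive, which preserves near-Gaussianity better than clipping)
  and inter-bin intervals from N(250, 25) ms on a clock shared by both
  sides.
* Click trains for the auditory reanalysis are side-independent Poisson
  processes whose rates sum to 40 Hz with a log rate ratio uniform in
  +/-[0.5, 3.5], over cue durations uniform in 0.2-1.0 s. No
  simultaneous onset click is generated, so every click is informative.

## Observer models

Static signal-detection observers draw one estimate per side,
est_S ~ N(n_S, sigma(n_S)^2), and choose the larger; sigma(n) follows the
configured law (SV: k*n; LV: sqrt(k*n); SUB: 0 up to c then k*n; offset
SV: k0 + k*n; an explicit per-count table; or one of the eight
two-parameter variant models below). Exact ties are broken by a fair
coin, and an optional lapse replaces the choice with a fair coin.

Trial-history kernels add Sum_lags w(lag, outcome) * side(lag) to the
signed decision variable before thresholding, with separate reward and
error weights per lag; weights combine linearly over lags, which is the
generative counterpart of the additivity the history analysis tests.

The drift-diffusion observer integrates da = lam*a dt + sigma_a dW plus
per-pulse increments eta*C (eta ~ N(1, sigma_s^2)), with shared sensory
adaptation C multiplied by phi at each pulse and recovering to 1 with
time constant tau_phi; C(0) = 1 (the fixed point of the recovery
dynamics, which the description of the process leaves open). Sticky
bounds at +/-B stop integration. Two equivalent-in-law implementations
exist: a per-trial Euler-Maruyama reference (default step 0.1 ms;
flashes applied instantaneously at their onset step) and a vectorised
cohort engine that advances the Ornstein-Uhlenbeck segments between bin
onsets with their exact transition density. The cohort engine checks
bound crossings only at bin boundaries; for the parameter regimes used
here (B = infinity or B below the unit pulse size) this makes no
difference, and a statistical agreement test ties the two paths
together. Simultaneous left+right pulses see the same pre-update C and C
is scaled by phi once per pulse.

## The per-count noise fit

The central estimator treats the per-count noise magnitudes
sigma_0..sigma_N as free parameters of the choice likelihood
P(right) = Phi((n_R - n_L) / sqrt(sigma_{n_R}^2 + sigma_{n_L}^2)),
clipped to [1e-12, 1 - 1e-12]. Because the likelihood depends on the
data only through the contingency table over (n_L, n_R, choice), the
fit collapses 50k trials into at most 256 cells; L-BFGS-B inside the box
[1e-3, 50] with five log-spaced initial slopes (0.05-1.2) takes
milliseconds per fit. sigma_0 is free like the rest; counts never
observed are reported as undefined (NaN) and excluded downstream rather
than interpolated.

Bootstrap confidence intervals refit trial resamples (multinomial
resampling of the contingency cells, which is exactly trial resampling)
with the full multi-start list plus a warm start at the full-data
solution. The multi-start matters: rarely-observed counts sit on
likelihood plateaus, and warm-started refits alone under-disperse the
percentile intervals (verified against the true sampling spread of the
MLE over independent datasets). The point estimate reported is always
the full-data MLE; the bootstrap mean is reported alongside, never
conflated. Default 1000 resamples; the test suite and the acceptance
script use 100 (50 for the clicks pipeline) to keep runtimes in minutes
— bootstrap CIs at 100 resamples are marginally noisier but unbiased.

A corollary of pure scalar variability is an emergent lapse rate: with n
pulses against none, P(error) = 1 - Phi(1/k) independently of n, so
easy-trial errors need no explicit lapse parameter.

## Scaling-law comparison

Laws are fit to the sigma table by weighted least squares, weights =
trials contributing to each count, all laws constrained through the
origin (offset variants add an intercept; the subitizing cutoff c is
chosen from {3, 4} by r^2, and no continuity at c is enforced — the law
jumps from 0). LV is fit in variance space but its r^2 is computed in
sigma space with the same weights, so all laws are compared on a common
scale. Discrimination uses the bootstrap distribution of r^2 (resample
trials, refit sigma table, refit law) and a permutation test on the
difference of distribution means: the two distributions are pooled and
split at random into two equal groups (odd pools give the extra draw to
one group at random); p-values use add-one smoothing, so the smallest
reportable p is 1/(n_perm+1).

## The eight accumulator variants

Three binary assumptions generate eight models, all with exactly two
free parameters (beta1, beta2 >= 0) so best-fit log-likelihoods are
directly comparable: single vs dual accumulators (noise indexed by the
count difference vs the counts per side), static vs sequential sampling
(noise on the final value vs an independent draw per pulse scaled by the
accumulator value at that pulse), and SV vs LV noise laws. For the
sequential models the accumulator value entering sigma(.) is the
deterministic expected path — the magnitude of the running difference
for the single accumulator, and each side's own running count (1..n_R
and 1..n_L) for the dual ones, since in a dual architecture a pulse
perturbs the accumulator it updates. Independent noise draws per pulse
are assumed, so variances sum along the path; this keeps every variant's
likelihood closed-form Gaussian with per-trial sufficient statistics
(sums of v and v^2 along the path), and fits are a 2-d bounded
multi-start search.

Ranking fits every variant to the same bootstrap resamples of the trial
table. Pairwise comparisons of the winner against each other model are
reported with two p-values: the pooled-split permutation test on the two
log-likelihood distributions, and a sign-flip permutation test on the
per-resample *paired* differences. The paired test is the sharper one:
the two distributions share their resampling noise (~70-90 nats SD at
20k trials) while the paired differences isolate the model gap (~10-15
nats with ~5 nats SD for the closest competitors), so it resolves model
gaps the pooled test cannot. Rankings whose winner and runner-up
distributions overlap are
flagged (small cohorts, of order 2k trials, do not support a stable
ranking).

## Model-free metrics

*Reverse correlation* pools trials with one fixed bin count (default 8)
and fixed generative probabilities, averages the per-bin count
difference conditioned on choice, and subtracts the expected difference
(+0.4 per bin on correct trials, -0.4 on errors, under 70%/30%); the
went-left curve is negated into excess-right units. Flat curves mean
uniform temporal weighting (accumulation time constant longer than the
trial); a leaky integrator weights late bins more, producing a rising
curve.

*Performance regressions.* Percent correct per (|diff|, total) cell is
centred on its |diff|-stratum weighted mean and regressed on the total
(% per flash); centring within (|diff|, total) cells and regressing on
50-ms-binned trial duration gives the % per second slope. Cells below
10 trials are dropped. Count-indexed noise makes the first slope
negative and leaves the second at zero; diffusion noise does the
reverse.

*Ratio analysis* groups trials by reduced low:high count ratio and scale
factor; under pure SV the model prediction is exactly flat within a
ratio group (the scale cancels), and inflated sigma at small counts
bends the small-scale end down.

*History.* The lag profile is P(current choice matches the side chosen
l trials back), split by whether that trial was rewarded or an error,
against the marginal-side-probability null. Two caveats drove the
design: (i) marginal repeat probabilities at long lags pick up
second-order "chains" (a reward three back biases the intervening
choices, which were themselves rewarded...), so the kernel is also
recovered by a joint probit regression of choice on signed past-outcome
regressors at all lags — the joint fit absorbs the chain into the short
lags and leaves true-zero long-lag coefficients at zero; (ii) the
additivity test conditions on *at least* m consecutive same-side rewards
(not exactly m), which makes "null + sum of single-lag biases" the
correct additive prediction up to the Phi nonlinearity.

*Duration vs number* uses jittered-duration trials: on equal-count
trials only the summed flash durations differ, and the slope of choice
on (durR - durL)/(durR + durL) is compared against zero and against the
all-trials duration slope. The verdict is "number" when the slope is
consistent with zero and inconsistent with the duration reference, and
"duration" when significantly positive — the equal-count slope of a true
duration integrator can exceed the all-trials reference, which is
attenuated by saturation at extreme ratios, so equality with the
reference is deliberately not required.

## Clicks reanalysis

Each click's effective magnitude is the adaptation state C at its time:
C relaxes toward 1 as C(t) = 1 - (1-C) exp(-dt/tau_phi) between events
and is multiplied by phi at each event after contributing its pre-update
value. One state is shared across sides by default (both event streams
drive the same adaptation; a per-side-state variant is available since
the side-coupling is a modelling choice). Per-side sums are rounded to
the nearest integer, halves away from zero, and handed to the per-count
fit; the offset laws sigma = k0 + k n and sigma^2 = k0 + k n are then
compared by the same bootstrap + permutation machinery. The adaptation
parameters are inputs, not fitted (phi = 0.5 with tau_phi = 50 ms for
the synthetic cohorts, chosen so effective counts span ~0-25 at 40 Hz —
a range over which the two offset laws actually differ); the synthetic
clicks observer uses k0 = 2, k = 0.3, echoing the magnitude reported for
auditory data relative to the much smaller visual offset.

## Problem sizes and determinism

All stochastic stages take a seed and are exactly reproducible; pipeline
JSON artifacts carry version, config hash and seed and contain no
timestamps, so reruns are byte-identical. The test suite and acceptance
script use cohorts of 20k-50k trials (parameter recovery and law
discrimination at 50k, variant ranking at 20k, clicks at 40k), 100
bootstrap resamples (25 for variant ranking, 50 for clicks) and 1000
permutations — sizes at which every qualitative conclusion the package
is designed to reach is stable across seeds, while a full run stays
within minutes on one core. Permutation conclusions were checked to be
stable across 100-10000 permutations.

## What the synthetic data do and do not show

The generator reproduces the stimulus statistics and a family of
explicit choice models; passing tests therefore demonstrate that the
estimators recover known generative truths (parameter recovery,
law/variant classification, kernel recovery, null calibration) at
realistic trial counts. They do not demonstrate anything about real
rats: real data mix sessions and subjects with drifting parameters,
motivational lapses, stimulus-independent biases and non-additive
history effects that the generator does not emulate. The deviations of
fitted sigma at rarely-observed counts (plateaued likelihoods at counts
that almost never co-occur with near-equal counts) are visible in
synthetic fits exactly as they are in behavioral ones, and the CIs are
honest about them.

## Known limitations

* The sequential variants use the deterministic expected accumulator
  path inside sigma(.); a stochastic-path observer is approximated, not
  matched (its per-flash noise would feed back into later noise scales).
  The approximation error is invisible at the parameter scales used here
  but has not been characterised at large beta.
* The clicks adaptation parameters are not estimable from choice data in
  this package; they must come from elsewhere.
* The DDM exists for data generation and property checks only; no
  likelihood-based DDM fitting is provided.
* Percentile bootstrap CIs at rarely-observed counts inherit the
  flatness of the likelihood; they are wide, not wrong, but a profile
  likelihood would characterise those counts better.
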