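# pulsecount

Where does the noise live in pulsatile evidence accumulation?

In two-alternative pulse-count discrimination, a subject watches two
streams of brief pulses (e.g. LED flashes to the left and right visual
hemifields, in 250-ms bins) and reports which side delivered more.
Drift-diffusion accounts of such decisions assume independent noise per
pulse, so the standard deviation of the accumulated count estimate grows
as the square root of the pulse count ("linear variance", LV). The
numerical-cognition literature instead predicts *scalar variability*
(SV): the standard deviation grows linearly with the count, as it does in
timing and counting — and a *subitizing* variant (SUB) adds noiseless
representation of counts up to 3-4. `pulsecount` is a toolkit for
separating these hypotheses from trial-level choice data, aimed at
psychophysicists and computational neuroscientists analysing pulse-based
accumulation tasks.

## The model at its core

The subject's estimate of the pulse count `n` on each side is modelled as
a Gaussian random variable with mean `n` and free standard deviation
`σ_n`; the choice is the side with the larger draw, so

    P(choose right) = Φ( (n_R − n_L) / √(σ_{n_R}² + σ_{n_L}²) )

The vector `σ_0 … σ_N` is fit to the observed choices by maximum
likelihood, with confidence intervals from refitting bootstrap resamples.
The scaling laws `σ_n = k·n` (SV), `σ_n² = k·n` (LV) and the subitizing
law are then fit to the `σ_n` by weighted least squares and compared via
bootstrap distributions of r² and a nonparametric permutation test.
A corollary of pure SV is an *emergent lapse rate*: with n pulses against
none, P(error) = 1 − Φ(1/k) independent of n, so imperfect easy-trial
performance needs no lapse parameter.

Around this core the package provides:

* `pulsecount.synthetic` — a stimulus generator with the task's exact
  statistics (250-ms bins, 10-ms flashes, per-trial Bernoulli generative
  probabilities 70–80% / 20–30%, variable trial durations, jittered
  variants, Poisson click trains) and observer models to drive it:
  SDT observers under any noise law, additive trial-history kernels, and
  a pulse-driven drift-diffusion simulator with sensory adaptation and
  sticky bounds.
* `pulsecount.variants` — the eight two-parameter accumulator models
  (single vs dual accumulators × static vs sequential noise × SV vs LV),
  their closed-form likelihoods, and a bootstrap + permutation ranking.
* `pulsecount.metrics` — model-free analyses: psychophysical reverse
  correlation, performance-vs-count and performance-vs-duration
  regressions, ratio-invariance curves, trial-history biases, and the
  flash-number-vs-flash-duration dissociation.
* `pulsecount.clicks` — the auditory reanalysis: per-click sensory
  adaptation (multiplicative depression φ with exponential recovery
  τ_φ), integer "effective" click counts, and the offset noise laws
  `σ = k₀ + k·n` vs `σ² = k₀ + k·n`.
* `pulsecount.cli` — a `pulsecount` console command chaining
  simulate → fit → compare into reproducible JSON artifacts.

No behavioral data ship with the package; every analysis is exercised on
synthetic cohorts with known generative truth. See `docs/methods.md` for
the full model descriptions and design choices.

## Worked example

Simulate 20k trials from a scalar-variability observer (k = 0.3) on the
freely-moving stimulus set, fit the per-count noise, and compare laws:

```python
import pulsecount as pc

cfg = pc.StimulusConfig.unrestrained()
table = pc.simulate_cohort(cfg, pc.ObserverSpec("sv", {"k": 0.3}),
                           n_trials=20_000, seed=7)
sig = pc.fit_sigma_table(table, n_max=15, n_boot=100, seed=8)
print(pc.fit_law(sig, "SV").k)          # fitted SV slope
res = pc.classify_scaling(table, n_boot=100, n_perm=1000, seed=9)
print(res["winner"], res["mean_r2"])
```

The same chain as a pipeline, `pulsecount run --config demo.yaml` with

```yaml
seed: 7
out_dir: demo_out
stages:
  - simulate: {observer: sv, k: 0.3, n_trials: 20000, preset: unrestrained}
  - summary:
  - fit_sdt: {n_boot: 100}
  - compare_scaling: {laws: [SV, LV, SUB_SV], n_boot: 100, n_perm: 1000}
  - report:
```

writes `demo_out/report.txt`:

```
pulsecount 0.1.0 run (seed=7)

simulated 20000 trials (sv observer)
20000 trials, 93.8% correct overall, 100.0% on the easiest stratum
per-count noise sigma_n (MLE):
  n= 0  sigma= 0.001  CI[0.001,0.130]
  n= 1  sigma= 0.266  CI[0.001,0.319]
  n= 2  sigma= 0.576  CI[0.530,0.644]
  n= 3  sigma= 0.982  CI[0.899,1.085]
  ...
  n=13  sigma= 3.896  CI[3.118,4.433]
noise-scaling comparison (mean bootstrapped r^2): SV=0.964, LV=0.750, SUB_SV=0.778
winner: SV; vs LV: p=0.000999; vs SUB_SV: p=0.000999
```

Read it as follows: the fitted `σ_n` rise close to the generating line
`0.3·n` (rarely-observed extreme counts have honest, wide intervals), the
weighted r² of the linear-σ law beats both alternatives across 100
bootstrap refits, and the permutation test puts the difference at the
resolution floor of 1000 permutations — the cohort is correctly
identified as a scalar-variability observer.

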