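# histddm

**History-biased bounded-accumulation models of perceptual choice:
simulation, quantile-likelihood fitting, and model recovery.**

Perceptual decisions are pulled toward (or pushed away from) the previous
choice even when the stimulus sequence is random. `histddm` is a library
for asking *where in the decision process* that bias lives: in the
starting point of evidence accumulation, or in the accumulation itself.
It provides:

* Monte-Carlo simulators for the drift diffusion model (DDM) and
  leaky-accumulator families with choice-history biases — starting-point
  shift, drift bias, ramping drift bias, input bias, and a λ (leak)
  asymmetry between two racing accumulators — under static or collapsing
  decision bounds, driven by scalar per-trial evidence or by time-varying
  evidence traces;
* quantile maximal likelihood (QMPE) fitting: empirical RTs binned by
  their 0.1/0.3/0.5/0.7/0.9 quantiles per difficulty × response × history
  cell, model bin probabilities estimated by simulating replicates of
  every experimental trial, and a multi-stage bounded Nelder-Mead search;
  group-level AIC model comparison;
* model-free diagnostics: signal-detection d′, P(repeat), conditional
  bias functions (the RT-resolved signature that separates starting-point
  from accumulation biases), outcome-conditioned strategy classification,
  and psychophysical kernels;
* across-observer inference: Spearman correlations, a dependent-
  correlation (shared-variable) z test, default Bayes factors for
  correlations with cross-dataset multiplication, and exponential
  history-kernel fits;
* the effective-bias time course (cumulative bias as a fraction of the
  momentary bound);
* a synthetic-data layer generating full observer cohorts with known
  ground truth and *endogenous* history (each trial's "previous choice"
  is the model's own previous simulated choice), used for parameter- and
  model-recovery studies.

The core model: a decision variable accumulates noisy evidence,
dy = (g·v̈ + bias terms)·dt + c·dW, between two absorbing bounds; choice =
bound reached, RT = crossing time + non-decision time. A starting-point
bias (y₀ = a/2 + z_bias·prev) biases mainly fast decisions; a drift bias
(+ v_bias·prev in the drift) biases slow decisions too. That asymmetry is
what the fitting and the conditional bias functions exploit.

## Worked example

```python
from histddm import (CohortSpec, FitConfig, ModelSpec, fit_model,
                     generate_cohort, p_repeat)

cohort = CohortSpec(n_subjects=1, n_trials=1500, master_seed=11,
                    param_distributions={"v_bias": ("constant", 0.4)})
trials, _ = generate_cohort(cohort, ModelSpec("ddm_default", "drift_bias"))
print(f"P(repeat) = {p_repeat(trials):.3f}")

fit = fit_model(ModelSpec("ddm_default", "hybrid"), trials, FitConfig.smoke(seed=3))
print(f"v_bias = {fit.params.v_bias:+.3f}, z_bias = {fit.params.z_bias:+.3f}")
```

Output (examples/03_fit_and_recover.py):

```
generated 1500 trials, P(repeat) = 0.546
fitted drift bias   v_bias = +0.529  (truth +0.400)
fitted start shift  z_bias = -0.011  (truth +0.000)
log-likelihood -4932.0, AIC 9878.0
```

The observer was generated with a pure repetition drift bias of 0.4
(raising P(repeat) from 0.5 to 0.55); the hybrid fit, which could have
placed the bias on either mechanism, returns it on the drift parameter
with the generating sign while the starting-point shift stays near zero.
The `examples/` directory has one short script per capability: bias
signatures in conditional bias functions, oracle validation of the
simulator, fitting and recovery, AIC model comparison, effective-bias
dynamics, and cohort-level inference.

A thin CLI mirrors the main workflows
(`histddm simulate|fit|compare|analyze|recover|effbias`); every run writes
a manifest with its seeds and configuration.

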