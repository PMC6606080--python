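# Methods

## The problem

Perceptual choices are systematically attracted to (or repelled from) the
immediately preceding choice even when stimuli are serially independent.
Within bounded-accumulation models of decision-making, two mechanisms can
produce such a choice-history bias: a shift of the accumulator's *starting
point* toward the bound of the previous choice, or a shift of the
*accumulation* itself (a drift-rate offset, or an evidence-weighting
asymmetry in a leaky accumulator). The two mechanisms are behaviorally
separable through response times: a starting-point shift acts before
evidence arrives and therefore biases mainly fast decisions, while an
accumulation bias grows with elapsed time and biases slow decisions too.
This package implements the simulation, fitting, and inference machinery
needed to make that separation on trial-level choice/RT data, and a
synthetic-data layer that closes the loop with parameter- and
model-recovery studies.

## Models

### Default-protocol DDM

The decision variable follows dy = g·v̈·dt + c·dW between absorbing bounds
at 0 and a, starting at y0 = a/2 + U(−sz, sz). The per-trial effective
drift v̈ ~ N(m, sv²), where m is the scalar evidence of that trial (the
signed, time-averaged sensory input) and sv is drift-rate variability. The
noise SD is fixed at c = 1 so g sets the signal-to-noise ratio. History
biases are keyed to the previous choice prev ∈ {−1, +1}:

| variant        | mechanism                                      | extra parameters |
|----------------|------------------------------------------------|------------------|
| starting point | y0 += z_bias·prev                              | z_bias |
| drift bias     | drift += v_bias·prev                           | v_bias |
| hybrid         | both of the above                              | z_bias, v_bias |
| ramp           | drift += s_ramp·(t/t_max)·prev                 | s_ramp |
| hybrid ramp    | drift += (s_constant + s_ramp·t/t_max)·prev    | s_constant, s_ramp |

The Euler step is dt = 5 ms; the process times out after 300 steps
(1500 ms), assigning the choice by the sign of y − a/2 (seeded fair coin at
an exact tie). RT = non-decision time ter + first-passage time.

### Dynamic protocol and leaky accumulators

In the dynamic protocol the input is a per-trial evidence time series M_t
(150 samples of 5 ms for a 750 ms viewing period; raw 60 Hz traces are
trimmed of their first 15 rise-time samples and constant-interpolated
5×). Accumulation starts at stimulus onset; responses may occur during
viewing. After offset the deterministic drive becomes the average
accumulated deviation per viewing step, and the process may run 300
further steps. Leaky accumulators add a term λ·u to the drift (u the
deviation from the neutral point): λ < 0 decays past evidence (recency),
λ > 0 self-amplifies it (primacy). The λ-bias variant evolves two racing
accumulators receiving the rectified halves of the input stream, each with
noise variance c²/2, with effective leaks λ_A = λ + max(prev, 0)·λ_bias and
λ_B = λ + max(−prev, 0)·λ_bias; the decision variable is their difference
with symmetric bounds ±a. Collapsing bounds follow the hyperbola
b_up(t) = a − a·t/(t + c_collapse), clamped at the midpoint (single
accumulator) or collapsing to 0 (two-accumulator race).

Two conventions exist in the literature for the sign of λ in such models;
the `lambda_sign_convention` flag selects between reading the λ·y term
literally (`positive_excites`: positive λ self-excitatory) and the
reporting convention in which negative values denote self-excitation
(`negative_excites`). The recovery-grid presets use the latter, so the
listed λ = −2.5 produces the primacy regime.

### Coordinates and symmetry

All scalar kernels integrate the *deviation* u = y − neutral rather than y
itself; the leak acts on u. This makes an unbiased model exactly
antisymmetric under a sign flip of the inputs, keeps the zero-input choice
fraction at 1/2, and equals the two-accumulator difference dynamics
re-centered at the neutral point. For the same reason the post-offset
drive is (y(T) − neutral)/T per step: the literal uncentered average would
inject a spurious drift toward the upper bound of order a/(2T) per step in
midpoint coordinates.

## Numerics

* **Brownian-bridge absorption.** Discrete-time bound checks miss paths
  that cross and return within one Euler step, inflating absorption times
  and distorting choice fractions by O(√dt) — at dt = 5 ms that error is
  ~0.017 in the absorption probability of the reference parameterization,
  two orders above Monte-Carlo error at 10⁵ traces. After each interior
  step, the kernels therefore cross a bound with the bridge probability
  exp(−2·(b−u_t)(b−u_{t+1})/(c²dt)). Crossings are dated at the step
  midpoint (removing the remaining +dt/2 bias in first-passage times).
  With both corrections the simulator matches the closed-form Wiener
  absorption probability and mean decision time within ~1 Monte-Carlo SE
  at 10⁵ traces.
* **Common random numbers.** The QMPE objective is simulation-based; all
  parameter-independent draws (start jitter, drift variability, Euler
  increments, tie-breaks) are frozen per fitting session, so the simplex
  descends a deterministic surface. The bridge uniforms come from a
  counter-based per-trace LCG, deterministic in the seed and free of
  memory traffic. Noise banks are LRU-cached, which removes RNG generation
  from the inner fitting loop.
* **Initial simplex.** Nelder-Mead is started with vertex steps of 8% of
  each parameter's box width (3% in the refinement stage). scipy's default
  perturbs zero-valued coordinates by 2.5e−4, which leaves any bias
  parameter started at exactly 0 unexplorable.

## QMPE fitting

Empirical RTs are binned by their 0.1/0.3/0.5/0.7/0.9 quantiles (type-7
interpolation; ties to the lower bin) within each cell of difficulty ×
response (correct/error) × history (stimulus consistent/inconsistent with
the previous choice). The default difficulty pooling excludes the easiest
coherence (81%) and pools 0% with 3%, giving 3 × 2 × 2 × 6 = 72 bins.
Sparse cells (< 6 trials) collapse to a 2-bin median split so the total
count is conserved; empty or fully tied cells keep a single bin. Model
probabilities come from simulating n_rep replicates of every experimental
trial, classifying each synthetic response into the empirical bins
(timeouts enter the top bin of their cell), flooring unvisited bins at
10⁻⁵ and renormalizing. The log-likelihood is Σ_k n_k ln P_k and the
search is multi-stage: per session, the best of N uniform random candidate
sets (plus any warm starts) seeds a bounded Nelder-Mead run at the lowest
replication factor; session winners are re-scored on a common fresh seed
at the middle factor; the best few are re-refined; the single winner is
re-scored at the highest factor. An optional convergence control stops
launching sessions once two independent restarts agree within a tolerance
on the common re-scoring seed.

Presets (replication factors / sessions): `full` (10/20/30, 50 fixed
sessions), `smoke` (5/10/15, ≤ 8 sessions with agreement stopping),
`lean` (2/6/12, ≤ 6 sessions; used for large fit batteries). The recovery
analyses in the test-suite and acceptance script use `smoke` for the
24-observer hybrid recovery and `lean` for the identification and
cross-fitting batteries; these sizes keep the full recovery surface at
roughly twenty minutes of single-core compute.

Box bounds for the search: a ∈ [0.3, 3], g ∈ [0.05, 10], ter ∈ [0, 0.5] s,
sv ∈ [0, 2], sz ∈ [0, 0.45·a], z_bias ∈ [−0.4·a, 0.4·a], v_bias and
s_constant ∈ [−2, 2], s_ramp ∈ [−5, 5] /s, λ ∈ [−10, 10] /s,
λ_bias ∈ [−5, 5] /s, c_collapse ∈ [0.01, 10] s. sz and z_bias are searched
as fractions of a so the joint feasibility constraint holds throughout.

Model comparison uses group-level AIC = −2 Σ_s ln L_s + 2 m_f; an absolute
difference above 10 is treated as decisive. History shifts are oriented so
positive = repetition; with prev-coded biases the shift equals twice the
coded parameter.

## Synthetic data

The generator emulates a coarse-coherence random-dot task: stimulus
categories follow a two-state chain (repeat probability 0.5 by default,
i.e. serially independent), strengths are drawn from
{0, 3, 9, 27, 81}% coherence, and the canonical evidence mapping is
m = 6·coherence/100 drift units — spanning near-chance (3%) to
near-perfect (81%) accuracy for a unit-gain observer. Evidence traces add
an AR(1) perturbation with selectable stationary SD and smoothing time
constant. Behavior is generated *sequentially*: each trial's prev is the
model's own previous simulated choice within the session (sessions of 500
trials by default; the first trial of each session carries no history), so
choice repetition is an emergent property of the generating mechanism.
Baseline generating parameters are a = 1, g = 1, ter = 0.1 s, sv = 0.5,
sz = 0 (DDM) and a = 0.42, λ = −2.5 (negative-excites convention), g = 1
(leaky race); recovery grids use starting-point offsets {0.06, 0.12,
0.18}, drift biases {0.2, 0.5, 0.8}, ramps {1.5, 2.5, 3.5}/s, leaky
starting points {0.05, 0.10, 0.15}, input biases {0.2, 0.5, 0.8} and
accumulator-leak contrasts {(−3, −2), (−4, −1), (−5, 0)}.

What the generator does *not* emulate: slow drifts of attention or
criterion, post-error slowing, lapses/contaminant responses, motor noise
beyond a fixed non-decision time, and multi-lag history kernels beyond the
lag-1 dependence the models themselves produce. Passing recovery tests
therefore shows that the estimation machinery is consistent — that the
fitted bias parameters mean what they claim when the model family is
right — not that real data satisfy these models.

## Model-free layer

d′ = Φ⁻¹(H) − Φ⁻¹(FA) with both proportions clamped to [0.001, 0.999];
for 2AFC data one category is (arbitrarily, by configuration) treated as
signal absent. P(repeat) is the fraction of history-valid trials repeating
the previous choice. Conditional bias functions split each observer's RTs
into five equal-mass quintile bins (labeled by the representative
quantiles 0.1…0.9) and report the fraction of choices in the observer's
own bias direction (repeat if P(repeat) > 0.5; ties resolved to repeat
with a warning). Psychophysical kernels subtract choice-conditioned mean
evidence traces within each stimulus identity, excluding the easiest
level, then average identities.

## Inference layer

Across-observer correlations are Spearman rank correlations (average
ranks; large-sample p; Fisher-transform CI). Two dependent correlations
sharing an observer-level variable are compared with the
Fisher-z dependent-correlation test (the shared-variable case), whose
type-I error is verified ≤ 0.06 at α = 0.05 over 10⁴ simulated null
cohorts. The correlation Bayes factor is the exact default-prior BF
(stretched-beta with κ = 1, i.e. a uniform prior on the coefficient),
computed via pingouin; per-dataset BF10 values multiply into a combined
evidence measure. Exponential history-kernel fits V_t = A·e^(−t/τ) use
bounded least squares with τ ∈ (0, 100]; a τ pinned at the upper bound
flags a non-decaying kernel. Repetition at lag k ≥ 2 can be corrected by
the two-state Markov expectation 0.5 + 0.5·(2p₁ − 1)^k implied by the
lag-1 repetition probability p₁ (`markov_lag1_correction`), which removes
the repetition trivially inherited from the lag-1 bias.

## Effective bias signal

The effective bias at time t is the noise-free cumulative bias — the
difference between the model's mean trajectory with and without its bias
terms, prev fixed at +1 — divided by the momentary upper bound. For a
constant drift bias with static bounds this is exactly v_bias·t/a; bound
collapse and/or self-excitatory leak make it supra-linear. The λ-bias
variant has no noise-free cumulative bias (its asymmetry acts on the
amplification of evidence, not on a mean bias trajectory), and is reported
as zero with a warning. For cohorts of leaky fits, curves are computed per
λ-sign group (averaging parameters within group, with |v_bias| to emulate
repetition) and their pointwise mean is reported alongside.

## Degenerate inputs and edge rules

First trials of a session (no history) are excluded from all
history-conditioned computations. Sessions shorter than the requested lag
yield missing lagged columns. An exactly tied quantile edge sends the tied
RT to the lower bin. A cell whose RTs are all identical keeps its entire
mass in one bin and warns. A fitted parameter landing on a box bound is
recorded in the fit's stage log as a convergence warning. Infeasible
(sz, z_bias) combinations proposed by the optimizer receive a graded
penalty rather than an exception; the public simulators raise before
running any trace.

## Known limitations

* Likelihoods are simulation-based; at the `lean` replication factors the
  effective likelihood surface is noticeably noisy, and fitted bias
  magnitudes (not ranks) can be biased for weakly constrained parameter
  combinations (sv–sz–a trade-offs at a few thousand trials).
* The dynamic-protocol and leaky fits require per-trial evidence traces;
  fitting them to trace-free data is not supported by construction.
* No contaminant/lapse mixture is included in the simulators; data with
  substantial lapses will inflate sv and ter instead.
* Hierarchical (group-prior) estimation is out of scope; every observer is
  fit independently.
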