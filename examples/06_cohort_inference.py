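"""Across-observer inference on a synthetic cohort.

Observers differ only in their drift-bias history shift.  Individual
P(repeat) should rank-correlate with the true shift; the Bayes factor
quantifies the evidence, and an exponential fit summarizes how a multi-lag
history kernel decays.
"""

import numpy as np

from histddm import (
    CohortSpec, ModelSpec, bf_correlation, combine_bf, fit_exponential_kernel,
    generate_cohort, p_repeat, spearman,
)

cohort = CohortSpec(
    n_subjects=16, n_trials=1200, master_seed=42,
    param_distributions={"v_bias": ("uniform", -0.4, 0.4)},
)
trials, truth = generate_cohort(cohort, ModelSpec("ddm_default", "drift_bias"))

shift = truth[truth.param == "v_bias"].sort_values("subject")["value"].to_numpy()
prep = np.array([p_repeat(trials[trials.subject == s]) for s in range(16)])

rep = spearman(2 * shift, prep)   # history shift = 2 * coded bias
rep.bf10 = bf_correlation(rep.rho, rep.n)
print(f"rho(true drift shift, P(repeat)) = {rep.rho:.3f}, p = {rep.p:.2e}, BF10 = {rep.bf10:.1f}")
print(f"combined over two such cohorts the BF product would be {combine_bf([rep.bf10, rep.bf10]):.1f}")

# exponential decay of a lagged history kernel
lags = np.arange(1, 7)
weights = 0.8 * np.exp(-lags / 2.0)
k = fit_exponential_kernel(weights, lags)
print(f"noiseless kernel fit: amplitude {k.amplitude:.3f} (true 0.800), "
      f"tau {k.tau:.3f} lags (true 2.000)")
print("BF10 > 10 = substantial evidence for a real correlation; tau is the")
print("memory timescale of the history bias in units of trials.")
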