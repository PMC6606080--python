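"""Simulate biased observers and read the RT-resolved bias diagnostic.

A starting-point bias and a drift bias produce the same overall choice
asymmetry but different conditional bias functions (CBF): the starting
point acts before evidence arrives, so its effect is concentrated in the
fastest responses; a drift bias grows with accumulation time, so biased
choices persist into the slowest responses.
"""

import numpy as np

from histddm import (
    CohortSpec, ModelSpec, conditional_bias_function, generate_cohort, p_repeat,
)

for label, spec, dist in [
    ("starting-point bias", ModelSpec("ddm_default", "starting_point"),
     {"z_bias": ("constant", 0.18)}),
    ("drift bias", ModelSpec("ddm_default", "drift_bias"),
     {"v_bias": ("constant", 0.5)}),
]:
    cohort = CohortSpec(n_subjects=1, n_trials=4000, master_seed=7,
                        param_distributions=dist)
    trials, _ = generate_cohort(cohort, spec)
    cbf = conditional_bias_function(trials)
    print(f"{label}:")
    print(f"  P(repeat) = {p_repeat(trials):.3f}  (0.5 = unbiased)")
    print("  CBF (fraction bias-consistent per RT quintile, fast -> slow):")
    print("   ", np.round(cbf.fraction_biased, 3))
    print(f"  fastest-vs-slowest bin difference: "
          f"{cbf.fraction_biased[0] - cbf.fraction_biased[4]:+.3f}")
    print()

print("Expected: the starting-point CBF decays toward 0.5 in slow bins;")
print("the drift-bias CBF stays above 0.5 across all bins.")
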