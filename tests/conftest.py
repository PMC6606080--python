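import warnings

import numpy as np
import pandas as pd
import pytest

from histddm import CohortSpec, ModelSpec, generate_cohort, validate_trials


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="cell .*")
        warnings.filterwarnings("ignore", message="fitted parameter.*")
        yield


def make_trials(choices, sessions=None, rts=None, stimuli=None, subject=0):
    """Small hand-built trial table from a choice sequence."""
    n = len(choices)
    df = pd.DataFrame(
        {
            "subject": subject,
            "session": sessions if sessions is not None else [0] * n,
            "trial": np.arange(n),
            "stimulus": stimuli if stimuli is not None else choices,
            "strength": 10.0,
            "choice": choices,
            "rt": rts if rts is not None else np.linspace(0.3, 0.9, n),
            "correct": None,
        }
    ).drop(columns=["correct"])
    return validate_trials(df)


@pytest.fixture(scope="session")
def drift_bias_observer():
    """One synthetic observer with a known repetition drift bias."""
    cohort = CohortSpec(
        n_subjects=1, n_trials=2000, master_seed=11,
        param_distributions={"v_bias": ("constant", 0.4)},
    )
    trials, truth = generate_cohort(cohort, ModelSpec("ddm_default", "drift_bias"))
    return trials, truth
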