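"""Synthetic cohorts with known ground truth.

Everything downstream (binning, fitting, model comparison, correlation
inference) is exercised on data generated here: i.i.d. or Markov stimulus
sequences at a ladder of coherence levels, evidence traces with
coherence-dependent mean and autocorrelated within-trial fluctuations, and
trial-by-trial behavior simulated from any implemented model.  History is
*endogenous*: each trial's ``prev`` is the model's own previous simulated
choice within the session, which is what makes choice-repetition behavior
an emergent property rather than an input.

The canonical mapping from signed coherence (in %) to the drift-units
evidence input is ``m = EVIDENCE_SCALE * strength / 100`` with
EVIDENCE_SCALE = 6, spanning near-chance (3%) to near-perfect (81%)
accuracy for a unit-gain observer; generators and fitters share it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .bounds import BoundSchedule, deviation_bounds
from .data_model import validate_trials
from .ddm import DT_DEFAULT, T_MAX_DEFAULT, _crossing_rt, bias_terms
from .dynamic import EvidenceTraces, N_POST_DEFAULT, effective_lambda
from .models import ModelSpec, ParamSet, SpecError

EVIDENCE_SCALE = 6.0
DEFAULT_COHERENCES = (0.0, 3.0, 9.0, 27.0, 81.0)


def trial_drift_input(trials: pd.DataFrame, evidence_scale: float = EVIDENCE_SCALE) -> np.ndarray:
    """Per-trial scalar evidence m (drift units) from signed strength in %."""
    return trials["strength"].to_numpy(dtype=float) / 100.0 * evidence_scale


def generate_stimuli(
    n_trials: int,
    coherence_levels=DEFAULT_COHERENCES,
    transition_prob: float = 0.5,
    seed: int = 0,
):
    """Signed stimulus categories and strengths.

    Categories follow a two-state chain with repeat probability
    ``transition_prob`` (0.5 = i.i.d., the default in most of the study's
    tasks); unsigned strengths are drawn uniformly from the level set.

    Returns
    -------
    (stimulus, strength) : arrays of ±1 and signed % coherence.
    """
    levels = np.asarray(list(coherence_levels), dtype=float)
    if levels.size == 0:
        raise ValueError("coherence_levels must be non-empty")
    if not 0 < transition_prob < 1:
        raise ValueError(f"transition_prob must be in (0,1), got {transition_prob}")
    rng = np.random.default_rng(seed)
    stim = np.empty(n_trials, dtype=np.int64)
    stim[0] = rng.choice([-1, 1])
    repeats = rng.random(n_trials - 1) < transition_prob
    for i in range(1, n_trials):
        stim[i] = stim[i - 1] if repeats[i - 1] else -stim[i - 1]
    strength = rng.choice(levels, size=n_trials) * stim
    return stim, strength


def generate_evidence_traces(
    strength,
    n_samples: int = 150,
    fluctuation_sd: float = 0.0,
    smoothing_tau: float = 0.05,
    dt: float = DT_DEFAULT,
    seed: int = 0,
    evidence_scale: float = EVIDENCE_SCALE,
) -> EvidenceTraces:
    """Evidence traces: coherence-proportional mean + AR(1) fluctuations.

    The perturbation is first-order smoothed with time constant
    ``smoothing_tau`` (lag-1 autocorrelation exp(-dt/tau)) and stationary SD
    ``fluctuation_sd``, emulating the within-trial variability of filtered
    sensory evidence.
    """
    strength = np.asarray(strength, dtype=float).ravel()
    if fluctuation_sd < 0:
        raise ValueError("fluctuation_sd must be >= 0")
    if smoothing_tau < dt:
        raise ValueError(f"smoothing_tau must be >= dt ({dt}), got {smoothing_tau}")
    mean = strength / 100.0 * evidence_scale
    vals = np.tile(mean[:, None], (1, n_samples))
    if fluctuation_sd > 0:
        rng = np.random.default_rng(seed)
        alpha = np.exp(-dt / smoothing_tau)
        innov_sd = fluctuation_sd * np.sqrt(1.0 - alpha**2)
        x = rng.normal(0.0, fluctuation_sd, size=strength.size)
        fluct = np.empty((strength.size, n_samples))
        eps = rng.normal(0.0, innov_sd, size=(strength.size, n_samples))
        for t in range(n_samples):
            fluct[:, t] = x
            x = alpha * x + eps[:, t]
        vals = vals + fluct
    return EvidenceTraces(vals, dt=dt)


def simulate_observer_trials(
    spec: ModelSpec,
    params: ParamSet,
    stimulus,
    strength,
    seed: int,
    m=None,
    traces: EvidenceTraces | None = None,
    dt: float = DT_DEFAULT,
    lambda_sign_convention: str = "positive_excites",
) -> pd.DataFrame:
    """Simulate one session of behavior with endogenous history.

    For the default protocol ``m`` defaults to the canonical drift input
    derived from strength; dynamic/leaky families require ``traces``.
    Returns the session as (unvalidated) canonical trial columns.
    """
    stimulus = np.asarray(stimulus, dtype=float).ravel()
    strength = np.asarray(strength, dtype=float).ravel()
    n = stimulus.size
    zb, vb, ramp = bias_terms(spec, params)
    seed32 = int(np.random.SeedSequence(seed).generate_state(1)[0])
    choice = np.empty(n, dtype=np.int64)
    steps = np.empty(n, dtype=np.int64)
    timed_out = np.empty(n, dtype=np.bool_)
    prev = np.empty(n, dtype=np.float64)

    if spec.family == "ddm_default":
        if m is None:
            m = strength / 100.0 * EVIDENCE_SCALE
        m = np.asarray(m, dtype=float).ravel()
        schedule = BoundSchedule(spec.bounds, params.a, params.c_collapse, "midpoint")
        bu, bl = deviation_bounds(schedule, T_MAX_DEFAULT, dt)
        _kernels.ddm_seq(
            params.g * m, params.g * params.sv, params.sz, zb, vb, ramp,
            bu, bl, dt, params.noise_c, seed32,
            choice, steps, timed_out, prev,
        )
    else:
        if traces is None:
            raise ValueError(f"family {spec.family} requires evidence traces")
        M = traces.values
        if M.shape[0] != n:
            raise ValueError("trace/trial count mismatch")
        n_view = M.shape[1]
        n_steps = n_view + N_POST_DEFAULT
        if spec.family == "ddm_dynamic":
            schedule = BoundSchedule(spec.bounds, params.a, params.c_collapse, "midpoint")
            bu, bl = deviation_bounds(schedule, n_steps, dt)
            _kernels.scalar_dyn_seq(
                M, 0.0, params.g, params.sz, zb, vb, ramp, n_view,
                bu, bl, dt, params.noise_c, seed32,
                choice, steps, timed_out, prev,
            )
        else:
            lam, lam_bias = effective_lambda(params, lambda_sign_convention)
            if spec.bias_type == "lambda_bias" or spec.bias_type in ("starting_point", "input_bias"):
                # the generating engine for all leaky variants is the
                # two-accumulator race (the scalar reduction is used on the
                # fitting side only)
                schedule = BoundSchedule(spec.bounds, params.a, params.c_collapse, "zero")
                bu, _ = deviation_bounds(schedule, n_steps, dt)
                _kernels.dual_seq(
                    M, lam, lam_bias, params.g, params.sz, zb, vb, n_view,
                    bu, dt, params.noise_c, seed32,
                    choice, steps, timed_out, prev,
                )
            else:
                raise SpecError(f"cannot generate from leaky bias_type {spec.bias_type!r}")
    rt = _crossing_rt(params.ter, steps, timed_out, dt)
    return pd.DataFrame(
        {
            "stimulus": stimulus.astype(int),
            "strength": strength,
            "choice": choice,
            "rt": rt,
            "correct": choice == stimulus,
            "timed_out": timed_out,
        }
    )


@dataclass
class CohortSpec:
    """Sampling plan for a synthetic observer cohort.

    ``param_distributions`` maps parameter names to sampling laws:
    ("constant", v), ("uniform", lo, hi) or ("normal", mu, sd).  Unlisted
    parameters take the baseline defaults below.  ``bias_heterogeneity``
    names the history parameters that vary across observers (metadata for
    recovery scoring).
    """

    n_subjects: int = 24
    n_trials: int = 2000
    coherence_levels: tuple = DEFAULT_COHERENCES
    param_distributions: dict = field(default_factory=dict)
    bias_heterogeneity: tuple = ("v_bias",)
    master_seed: int = 0
    session_length: int = 500
    transition_prob: float = 0.5
    feedback: bool = True

    # baseline parameter values for anything not sampled
    baseline: dict = field(default_factory=lambda: {
        "a": 1.0, "g": 1.0, "ter": 0.1, "sv": 0.5, "sz": 0.0,
    })

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def _sample_params(dists: dict, baseline: dict, rng) -> ParamSet:
    for _ in range(100):
        kw = dict(baseline)
        for name, law in dists.items():
            kind = law[0]
            if kind == "constant":
                kw[name] = law[1]
            elif kind == "uniform":
                kw[name] = rng.uniform(law[1], law[2])
            elif kind == "normal":
                kw[name] = rng.normal(law[1], law[2])
            else:
                raise ValueError(f"unknown sampling law {kind!r} for {name}")
        try:
            return ParamSet(**kw)
        except SpecError:
            continue
    raise RuntimeError("could not sample a valid ParamSet in 100 attempts")


def generate_cohort(
    cohort: CohortSpec,
    generating_model: ModelSpec,
    trace_fluctuation_sd: float = 0.0,
    lambda_sign_convention: str = "positive_excites",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort; returns (trials, ground_truth).

    Trials carry canonical columns for all subjects; ground truth has one
    row per (subject, parameter).  Fully deterministic in master_seed.
    """
    ss = np.random.SeedSequence(cohort.master_seed)
    subj_seeds = ss.spawn(cohort.n_subjects)
    frames = []
    truth_rows = []
    for s_idx in range(cohort.n_subjects):
        child = subj_seeds[s_idx]
        rng = np.random.default_rng(child)
        params = _sample_params(cohort.param_distributions, cohort.baseline, rng)
        n_sessions = int(np.ceil(cohort.n_trials / cohort.session_length))
        sess_seeds = child.spawn(n_sessions)
        for sess in range(n_sessions):
            n_tr = min(cohort.session_length, cohort.n_trials - sess * cohort.session_length)
            sseed = int(sess_seeds[sess].generate_state(1)[0])
            stim, strength = generate_stimuli(
                n_tr, cohort.coherence_levels, cohort.transition_prob, seed=sseed,
            )
            traces = None
            if generating_model.family != "ddm_default":
                traces = generate_evidence_traces(
                    strength, fluctuation_sd=trace_fluctuation_sd, seed=sseed + 1,
                )
            df = simulate_observer_trials(
                generating_model, params, stim, strength, seed=sseed + 2,
                traces=traces, lambda_sign_convention=lambda_sign_convention,
            )
            df.insert(0, "trial", np.arange(n_tr))
            df.insert(0, "session", sess)
            df.insert(0, "subject", s_idx)
            frames.append(df)
        for name, value in params.to_dict().items():
            truth_rows.append({"subject": s_idx, "param": name, "value": value})
    trials = validate_trials(pd.concat(frames, ignore_index=True))
    if not cohort.feedback:
        trials["feedback"] = False
    else:
        trials["feedback"] = trials["correct"]
    truth = pd.DataFrame(truth_rows)
    return trials, truth
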