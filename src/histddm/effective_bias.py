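"""Within-trial time course of the effective bias signal.

The effective bias at time t is the noise-free *cumulative bias* — the
difference between the model's mean trajectory with and without its history
bias terms, for a previous choice fixed at +1 — divided by the momentary
upper bound b_up(t).  For a constant drift bias with static bounds this is
exactly linear in t; bound collapse and/or self-excitatory leak make it
supra-linear, i.e. the bias keeps growing as a fraction of the distance to
the bound late in the trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .bounds import BoundSchedule, bounds_at
from .ddm import DT_DEFAULT, T_MAX_DEFAULT, bias_terms
from .dynamic import effective_lambda
from .models import ModelSpec, ParamSet


@dataclass
class EffectiveBiasCurve:
    t: np.ndarray        # seconds, grid spacing = simulation dt
    value: np.ndarray    # cumulative bias / b_up(t), dimensionless
    model_tag: str


def effective_bias_curve(
    spec: ModelSpec,
    params: ParamSet,
    duration: float = 0.75,
    dt: float = DT_DEFAULT,
    prev: float = 1.0,
    lambda_sign_convention: str = "positive_excites",
) -> EffectiveBiasCurve:
    """Propagate the noise-free bias-only trajectory and scale by the bound.

    ``prev`` is fixed at +1 (repetition convention), so a repetition bias
    yields a positive curve.  The grid covers [0, duration] at the
    simulation step; ``duration`` defaults to the viewing period but may
    extend to the timeout cap.
    """
    zb, vb, ramp = bias_terms(spec, params)
    if zb == 0 and vb == 0 and ramp == 0 and (
        spec.bias_type != "lambda_bias" or params.lam_bias == 0
    ):
        warnings.warn("all bias parameters are zero: effective bias is identically 0")
    if spec.bias_type == "lambda_bias":
        # A λ asymmetry biases the *amplification* of evidence, not the
        # mean bias-only trajectory (the rectified zero input contributes
        # nothing); its effective bias signal is zero in this noise-free
        # parameter-level sense.
        warnings.warn("λ-bias has no noise-free cumulative bias signal; returning zeros")

    n_steps = int(round(duration / dt))
    t = np.arange(n_steps + 1) * dt
    asym = "zero" if (spec.family == "leaky" and spec.bias_type == "lambda_bias") else "midpoint"
    schedule = BoundSchedule(spec.bounds, params.a, params.c_collapse, asym)
    b_up, _ = bounds_at(schedule, t)

    lam = 0.0
    if spec.family == "leaky":
        lam, _ = effective_lambda(params, lambda_sign_convention)
    ramp_tmax = T_MAX_DEFAULT if spec.family == "ddm_default" else n_steps

    delta = np.empty(n_steps + 1)
    delta[0] = zb * prev
    d = delta[0]
    for k in range(n_steps):
        d += (lam * d + (vb + ramp * (k / ramp_tmax)) * prev) * dt
        delta[k + 1] = d
    return EffectiveBiasCurve(t, delta / b_up, spec.tag)


def effective_bias_by_lambda_sign(
    spec: ModelSpec,
    param_sets,
    duration: float = 0.75,
    dt: float = DT_DEFAULT,
    lambda_sign_convention: str = "positive_excites",
) -> dict:
    """Group-level effective bias curves for a cohort of leaky fits.

    Participants are split by the sign of their fitted λ; within each group
    the parameters are averaged (with the bias magnitude |v_bias| to emulate
    a repetition bias) and one curve computed per group.  Returns the two
    group curves and their pointwise average, which is what gets reported
    when the groups' time courses are similar.
    """
    param_sets = list(param_sets)
    if not param_sets:
        raise ValueError("need at least one ParamSet")
    groups: dict[str, list[ParamSet]] = {"lambda_pos": [], "lambda_neg": []}
    for p in param_sets:
        lam, _ = effective_lambda(p, lambda_sign_convention)
        groups["lambda_pos" if lam > 0 else "lambda_neg"].append(p)
    out: dict[str, EffectiveBiasCurve] = {}
    for name, members in groups.items():
        if not members:
            continue
        mean_kw = {
            f: float(np.mean([getattr(p, f) for p in members]))
            for f in ("a", "g", "ter", "sz", "lam", "c_collapse")
        }
        mean_kw["v_bias"] = float(np.mean([abs(p.v_bias) for p in members]))
        mean_kw["z_bias"] = float(np.mean([p.z_bias for p in members]))
        out[name] = effective_bias_curve(
            spec, ParamSet(**mean_kw), duration, dt,
            lambda_sign_convention=lambda_sign_convention,
        )
    curves = list(out.values())
    mean_val = np.mean([c.value for c in curves], axis=0)
    out["mean"] = EffectiveBiasCurve(curves[0].t, mean_val, spec.tag + ":group-mean")
    return out
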