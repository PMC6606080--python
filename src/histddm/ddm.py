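"""Default-protocol DDM simulation and closed-form first-passage oracles.

In the default simulation protocol the per-trial sensory evidence is a
single scalar ``m`` (e.g. the time-averaged motion energy), accumulation
runs after stimulus offset, and RT is non-decision time plus the first
passage time through one of two (possibly collapsing) bounds.  The Euler
step is 5 ms and the process times out after 300 steps (1500 ms), at which
point the choice is assigned by the sign of the decision variable relative
to the midpoint (seeded fair coin at an exact tie).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels, _noise
from .bounds import BoundSchedule, deviation_bounds
from .models import ModelSpec, ParamSet, SpecError

DT_DEFAULT = 0.005
T_MAX_DEFAULT = 300

# cap on traces*steps per kernel call, to bound the noise-bank memory
_CHUNK_ELEMENTS = 30_000_000


class SimulationError(RuntimeError):
    """Invalid simulation setup detected before any trace is run."""


@dataclass
class SimResult:
    """Outcome of a Monte-Carlo simulation run.

    ``choice``/``rt``/``timed_out`` have one entry per trace; ``trial_idx``
    maps each trace back to the input trial it replicates and ``prev`` holds
    the history signal that biased it.  ``rt`` includes non-decision time;
    timed-out traces carry rt = ter + n_steps*dt.
    """

    choice: np.ndarray
    rt: np.ndarray
    timed_out: np.ndarray
    trial_idx: np.ndarray
    prev: np.ndarray
    n_traces: int
    seed: int


def bias_terms(spec: ModelSpec, params: ParamSet) -> tuple[float, float, float]:
    """(starting-point shift, constant drift bias, ramp slope) active for a spec.

    Only the parameters belonging to the spec's bias mechanism are applied;
    stale fields in the ParamSet do not leak into other variants.
    """
    zb = vb = ramp = 0.0
    bt = spec.bias_type
    if bt in ("starting_point", "hybrid"):
        zb = params.z_bias
    if bt in ("drift_bias", "hybrid", "input_bias"):
        vb = params.v_bias
    if bt == "ramp":
        ramp = params.s_ramp
    if bt == "hybrid_ramp":
        vb = params.s_constant
        ramp = params.s_ramp
    return zb, vb, ramp


def _check_start(params: ParamSet, zb: float) -> None:
    if params.sz + abs(zb) >= params.a / 2:
        raise SimulationError(
            f"starting point outside (0, a): sz={params.sz}, |z_bias|={abs(zb)}, a={params.a}"
        )


def simulate_ddm(
    spec: ModelSpec,
    params: ParamSet,
    m,
    prev,
    n_rep: int = 1,
    seed: int = 0,
    dt: float = DT_DEFAULT,
    t_max: int = T_MAX_DEFAULT,
) -> SimResult:
    """Simulate the default-protocol DDM.

    Parameters
    ----------
    m
        Per-trial scalar evidence (signed); the effective drift of each
        trace is a fresh draw from N(m, sv^2), scaled by g.
    prev
        Per-trial previous choice in {-1, +1} (0 disables history bias for
        that trial, e.g. first of a session).
    n_rep
        Synthetic repetitions per trial; traces of the same trial are
        contiguous in the output.
    """
    if spec.family != "ddm_default":
        raise SpecError(f"simulate_ddm requires family ddm_default, got {spec.family}")
    m = np.asarray(m, dtype=float).ravel()
    prev = np.asarray(prev, dtype=float).ravel()
    if m.shape != prev.shape:
        raise ValueError("m and prev must have the same length")
    zb, vb, ramp = bias_terms(spec, params)
    _check_start(params, zb)

    schedule = BoundSchedule(spec.bounds, params.a, params.c_collapse, "midpoint")
    bu, bl = deviation_bounds(schedule, t_max, dt)

    n_trials = m.size
    n = n_trials * n_rep
    trial_idx = np.repeat(np.arange(n_trials), n_rep)
    prev_t = prev[trial_idx]

    choice = np.empty(n, dtype=np.int64)
    steps = np.empty(n, dtype=np.int64)
    timed_out = np.empty(n, dtype=np.bool_)
    cs = params.noise_c * np.sqrt(dt)
    chunk = max(1, _CHUNK_ELEMENTS // t_max)
    for lo in range(0, n, chunk):
        hi = min(n, lo + chunk)
        sl = slice(lo, hi)
        nn = hi - lo
        bank = _noise.noise_bank("scalar", seed, lo, nn, t_max)
        u0 = params.sz * bank["u"] + zb * prev_t[sl]
        veff = m[trial_idx[sl]] + params.sv * bank["v"]
        drift = params.g * veff + vb * prev_t[sl]
        ramp_coef = ramp * prev_t[sl]
        _kernels.ddm_grid(
            u0, drift, ramp_coef, bu, bl, dt, cs, bank["noise"], bank["tie"],
            np.uint64(int(seed) % (2**62) + lo),
            choice[sl], steps[sl], timed_out[sl],
        )
    rt = _crossing_rt(params.ter, steps, timed_out, dt)
    return SimResult(choice, rt, timed_out, trial_idx, prev_t, n, seed)


def _crossing_rt(ter: float, steps, timed_out, dt: float) -> np.ndarray:
    """RT from step counts: crossings are dated at the step midpoint.

    A crossing detected during step t happened somewhere inside the step, so
    t*dt would overestimate the first-passage time by dt/2 on average; the
    half-step shift removes that bias.  Timed-out traces keep the full cap.
    """
    rt = ter + (steps - 0.5) * dt
    return np.where(timed_out, ter + steps * dt, rt)


# ---------------------------------------------------------------------------
# Closed-form Wiener first-passage oracles (validation only)
# ---------------------------------------------------------------------------

def analytic_upper_prob(v: float, a: float, z: float, c: float = 1.0) -> float:
    """P(absorb at the upper bound) for a Wiener process on (0, a), start z.

    (1 - exp(-2 v z / c^2)) / (1 - exp(-2 v a / c^2)); the v -> 0 limit is
    z / a.
    """
    if not (0 < z < a):
        raise ValueError(f"start z must lie in (0, a), got z={z}, a={a}")
    if c <= 0:
        raise ValueError("noise SD c must be > 0")
    k = 2.0 * v / c**2
    if abs(v) < 1e-12 or abs(k * a) < 1e-12:
        return z / a
    return float(np.expm1(-k * z) / np.expm1(-k * a))


def analytic_mean_dt(v: float, a: float, c: float = 1.0) -> float:
    """Mean decision time for an unbiased start (z = a/2).

    (a / (2 v)) * tanh(v a / (2 c^2)); the v -> 0 limit is a^2 / (4 c^2).
    """
    if a <= 0 or c <= 0:
        raise ValueError("a and c must be > 0")
    if abs(v) < 1e-12:
        return a**2 / (4.0 * c**2)
    return float(a / (2.0 * v) * np.tanh(v * a / (2.0 * c**2)))
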