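"""Numba Euler-Maruyama kernels for bounded-accumulation simulation.

Two kinds of kernels live here:

* ``*_grid`` kernels consume a pre-drawn bank of standard-normal increments
  (common random numbers).  They are used by the fitting objective, where a
  deterministic likelihood surface is needed for the simplex search, and by
  the public simulators (the bank is drawn once from a seeded Generator, so
  results are bitwise reproducible).
* ``*_seq`` kernels generate behavior trial-by-trial with *endogenous*
  history: each trial's ``prev`` is the model's own previous simulated
  choice.  They use numba's internal RNG, seeded explicitly.

All scalar-accumulator kernels work in deviation coordinates ``u = y -
neutral`` (neutral = midpoint between the bounds), so an unbiased model is
exactly antisymmetric under sign flips of the input.  Bounds are passed as
per-step arrays ``bu[t]``/``bl[t]`` in the same coordinates, which covers
static and hyperbolically collapsing regimes alike.  A trace that survives
``nsteps`` steps times out: its choice is the sign of the deviation, with a
pre-drawn fair coin breaking an exact tie at zero.

Discrete-time absorption overestimates first-passage times (the path can
cross and return within one Euler step), so every kernel applies a
Brownian-bridge crossing correction: given endpoints strictly inside the
bounds, the bridge crosses the upper bound with probability
exp(-2 (bu - u_t)(bu - u_{t+1}) / (c^2 dt)).  This removes the O(sqrt(dt))
discretization bias and lets the simulators match continuous-time
first-passage oracles at dt = 5 ms.  Grid kernels draw the bridge uniforms
from a small per-trace counter-based LCG (deterministic in the seed), the
sequential kernels from numba's RNG.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "ddm_grid",
    "scalar_dyn_grid",
    "dual_grid",
    "ddm_seq",
    "scalar_dyn_seq",
    "dual_seq",
]

_LCG_A = np.uint64(6364136223846793005)
_LCG_C = np.uint64(1442695040888963407)
_MIX = np.uint64(0x9E3779B97F4A7C15)
_INV53 = 1.0 / 9007199254740992.0


@njit(cache=False, fastmath=True)
def _lcg_init(seed, i):
    s = (np.uint64(seed) + np.uint64(i + 1) * _MIX) | np.uint64(1)
    s = s * _LCG_A + _LCG_C
    s = s * _LCG_A + _LCG_C
    return s


@njit(cache=False, fastmath=True)
def _lcg_u01(s):
    s = s * _LCG_A + _LCG_C
    return (s >> np.uint64(11)) * _INV53, s


@njit(cache=False, fastmath=True)
def _finish(u, tie):
    """Timeout choice: sign of the deviation, seeded coin at exactly zero."""
    if u > 0.0:
        return 1
    if u < 0.0:
        return -1
    return 1 if tie < 0.5 else -1


@njit(cache=False, fastmath=True)
def _bridge_up(prev_gap, new_gap, var):
    """P(bridge crossed a bound) given endpoint distances to it."""
    e = -2.0 * prev_gap * new_gap / var
    if e >= 0.0:
        return 1.0
    if e < -30.0:   # p < 1e-13: skip the exp (and the caller skips its RNG draw)
        return 0.0
    return np.exp(e)


@njit(cache=False, fastmath=True)
def ddm_grid(u0, drift, ramp, bu, bl, dt, cs, noise, tie, seed,
             out_choice, out_steps, out_to):
    """Default-protocol DDM: constant per-trace drift plus optional ramp.

    Per-step mean increment: (drift[i] + ramp[i] * t / nsteps) * dt.
    ``cs`` is the pre-scaling noise_c * sqrt(dt) applied to the normal bank.
    """
    n = u0.shape[0]
    nsteps = noise.shape[1]
    inv2var = 2.0 / (cs * cs)
    for i in range(n):
        u = u0[i]
        rs = _lcg_init(seed, i)
        ddt = drift[i] * dt
        rdt = ramp[i] * dt / nsteps
        ch = 0
        st = nsteps
        to = True
        for t in range(nsteps):
            up = u
            u += ddt + rdt * t + cs * noise[i, t]
            but = bu[t]
            blt = bl[t]
            if u >= but:
                ch = 1
                st = t + 1
                to = False
                break
            if u <= blt:
                ch = -1
                st = t + 1
                to = False
                break
            eu = (but - up) * (but - u) * inv2var
            el = (up - blt) * (u - blt) * inv2var
            if eu < 30.0 or el < 30.0:
                pu = np.exp(-eu) if eu < 30.0 else 0.0
                pl = np.exp(-el) if el < 30.0 else 0.0
                r, rs = _lcg_u01(rs)
                if r < pu + pl:
                    ch = 1 if r < pu else -1
                    st = t + 1
                    to = False
                    break
        if to:
            ch = _finish(u, tie[i])
        out_choice[i] = ch
        out_steps[i] = st
        out_to[i] = to


@njit(cache=False, fastmath=True)
def scalar_dyn_grid(u0, lam, g, vb, ramp, trial_idx, M, dt, n_view, bu, bl, cs,
                    noise, tie, seed, out_choice, out_steps, out_to):
    """Dynamic-protocol scalar accumulator (leaky if lam != 0).

    During viewing (t < n_view) the increment is
    (lam*u + g*M[j,t] + vb[i] + ramp[i]*t/n_view) * dt; after stimulus
    offset the deterministic drive is replaced by the average deviation
    accumulated per viewing step, u(T)/n_view, while the leak keeps acting
    on the current state (the ramp applies to the viewing period only).
    """
    n = u0.shape[0]
    nsteps = noise.shape[1]
    var = cs * cs
    for i in range(n):
        j = trial_idx[i]
        u = u0[i]
        rs = _lcg_init(seed, i)
        ubar = 0.0
        ch = 0
        st = nsteps
        to = True
        for t in range(nsteps):
            up = u
            if t < n_view:
                u += (lam * u + g * M[j, t] + vb[i] + ramp[i] * t / n_view) * dt \
                    + cs * noise[i, t]
                if t == n_view - 1:
                    ubar = u / n_view
            else:
                u += lam * u * dt + ubar + cs * noise[i, t]
            if u >= bu[t]:
                ch = 1
                st = t + 1
                to = False
                break
            if u <= bl[t]:
                ch = -1
                st = t + 1
                to = False
                break
            pu = _bridge_up(bu[t] - up, bu[t] - u, var)
            pl = _bridge_up(up - bl[t], u - bl[t], var)
            if pu > 0.0 or pl > 0.0:
                r, rs = _lcg_u01(rs)
                if r < pu + pl:
                    ch = 1 if r < pu else -1
                    st = t + 1
                    to = False
                    break
        if to:
            ch = _finish(u, tie[i])
        out_choice[i] = ch
        out_steps[i] = st
        out_to[i] = to


@njit(cache=False, fastmath=True)
def dual_grid(uA0, lamA, lamB, g, vb, trial_idx, M, dt, n_view, bu, cs2,
              noiseA, noiseB, tie, seed, out_choice, out_steps, out_to):
    """Two-accumulator (λ-bias capable) race on the difference y = yA - yB.

    The raw input M[j,t] + vb[i] is split by threshold-linear rectifiers:
    yA integrates the positive part (coding choice +1), yB the sign-flipped
    negative part.  Each accumulator gets independent noise with SD
    noise_c/sqrt(2) so the difference has the DDM's noise variance.  Bounds
    are symmetric at ±bu[t]; the bridge correction is applied to the
    difference, whose per-step noise variance is 2*cs2^2.
    """
    n = uA0.shape[0]
    nsteps = noiseA.shape[1]
    var = 2.0 * cs2 * cs2
    for i in range(n):
        j = trial_idx[i]
        yA = uA0[i]
        yB = 0.0
        rs = _lcg_init(seed, i)
        ybarA = 0.0
        ybarB = 0.0
        ch = 0
        st = nsteps
        to = True
        for t in range(nsteps):
            uprev = yA - yB
            if t < n_view:
                x = M[j, t] + vb[i]
                inA = x if x > 0.0 else 0.0
                inB = -x if x < 0.0 else 0.0
                yA += (lamA[i] * yA + g * inA) * dt + cs2 * noiseA[i, t]
                yB += (lamB[i] * yB + g * inB) * dt + cs2 * noiseB[i, t]
                if t == n_view - 1:
                    ybarA = yA / n_view
                    ybarB = yB / n_view
            else:
                yA += lamA[i] * yA * dt + ybarA + cs2 * noiseA[i, t]
                yB += lamB[i] * yB * dt + ybarB + cs2 * noiseB[i, t]
            u = yA - yB
            if u >= bu[t]:
                ch = 1
                st = t + 1
                to = False
                break
            if u <= -bu[t]:
                ch = -1
                st = t + 1
                to = False
                break
            pu = _bridge_up(bu[t] - uprev, bu[t] - u, var)
            pl = _bridge_up(uprev + bu[t], u + bu[t], var)
            if pu > 0.0 or pl > 0.0:
                r, rs = _lcg_u01(rs)
                if r < pu + pl:
                    ch = 1 if r < pu else -1
                    st = t + 1
                    to = False
                    break
        if to:
            ch = _finish(yA - yB, tie[i])
        out_choice[i] = ch
        out_steps[i] = st
        out_to[i] = to


# ---------------------------------------------------------------------------
# Sequential generators: prev is the model's own previous simulated choice.
# ---------------------------------------------------------------------------

@njit(cache=False, fastmath=True)
def ddm_seq(m, sv, sz, zb, vb_const, ramp, bu, bl, dt, c, seed,
            out_choice, out_steps, out_to, out_prev):
    """Default-protocol DDM, one trace per trial, endogenous history."""
    np.random.seed(seed)
    n = m.shape[0]
    nsteps = bu.shape[0]
    cs = c * np.sqrt(dt)
    var = cs * cs
    prev = 0.0
    for i in range(n):
        out_prev[i] = prev
        u = np.random.uniform(-sz, sz) if sz > 0.0 else 0.0
        u += zb * prev
        veff = m[i] + sv * np.random.normal()
        drift = veff + vb_const * prev
        rmp = ramp * prev
        ch = 0
        st = nsteps
        to = True
        for t in range(nsteps):
            up = u
            u += (drift + rmp * t / nsteps) * dt + cs * np.random.normal()
            if u >= bu[t]:
                ch = 1
                st = t + 1
                to = False
                break
            if u <= bl[t]:
                ch = -1
                st = t + 1
                to = False
                break
            pu = _bridge_up(bu[t] - up, bu[t] - u, var)
            pl = _bridge_up(up - bl[t], u - bl[t], var)
            if (pu > 0.0 or pl > 0.0) and np.random.random() < pu + pl:
                ch = 1 if np.random.random() < pu / (pu + pl) else -1
                st = t + 1
                to = False
                break
        if to:
            ch = _finish(u, np.random.random())
        out_choice[i] = ch
        out_steps[i] = st
        out_to[i] = to
        prev = float(ch)


@njit(cache=False, fastmath=True)
def scalar_dyn_seq(M, lam, g, sz, zb, vb, ramp, n_view, bu, bl, dt, c, seed,
                   out_choice, out_steps, out_to, out_prev):
    """Dynamic-protocol scalar accumulator, endogenous history."""
    np.random.seed(seed)
    n = M.shape[0]
    nsteps = bu.shape[0]
    cs = c * np.sqrt(dt)
    var = cs * cs
    prev = 0.0
    for i in range(n):
        out_prev[i] = prev
        u = np.random.uniform(-sz, sz) if sz > 0.0 else 0.0
        u += zb * prev
        vbi = vb * prev
        rmp = ramp * prev
        ubar = 0.0
        ch = 0
        st = nsteps
        to = True
        for t in range(nsteps):
            up = u
            if t < n_view:
                u += (lam * u + g * M[i, t] + vbi + rmp * t / n_view) * dt \
                    + cs * np.random.normal()
                if t == n_view - 1:
                    ubar = u / n_view
            else:
                u += lam * u * dt + ubar + cs * np.random.normal()
            if u >= bu[t]:
                ch = 1
                st = t + 1
                to = False
                break
            if u <= bl[t]:
                ch = -1
                st = t + 1
                to = False
                break
            pu = _bridge_up(bu[t] - up, bu[t] - u, var)
            pl = _bridge_up(up - bl[t], u - bl[t], var)
            if (pu > 0.0 or pl > 0.0) and np.random.random() < pu + pl:
                ch = 1 if np.random.random() < pu / (pu + pl) else -1
                st = t + 1
                to = False
                break
        if to:
            ch = _finish(u, np.random.random())
        out_choice[i] = ch
        out_steps[i] = st
        out_to[i] = to
        prev = float(ch)


@njit(cache=False, fastmath=True)
def dual_seq(M, lam, lam_bias, g, sz, zb, vb, n_view, bu, dt, c, seed,
             out_choice, out_steps, out_to, out_prev):
    """Two-accumulator race, endogenous history.

    Effective leaks follow the rectified-prev rule: after a +1 choice the
    +1-coding accumulator's leak becomes lam + lam_bias, after a -1 choice
    the -1-coding accumulator's does.  Starting-point variability (and the
    optional starting-point bias zb*prev) is applied to yA only, which is
    equivalent to applying it to the difference.
    """
    np.random.seed(seed)
    n = M.shape[0]
    nsteps = bu.shape[0]
    cs2 = c * np.sqrt(dt) / np.sqrt(2.0)
    var = 2.0 * cs2 * cs2
    prev = 0.0
    for i in range(n):
        out_prev[i] = prev
        yA = (np.random.uniform(-sz, sz) if sz > 0.0 else 0.0) + zb * prev
        yB = 0.0
        lamA = lam + (lam_bias if prev > 0.0 else 0.0)
        lamB = lam + (lam_bias if prev < 0.0 else 0.0)
        vbi = vb * prev
        ybarA = 0.0
        ybarB = 0.0
        ch = 0
        st = nsteps
        to = True
        for t in range(nsteps):
            uprev = yA - yB
            if t < n_view:
                x = M[i, t] + vbi
                inA = x if x > 0.0 else 0.0
                inB = -x if x < 0.0 else 0.0
                yA += (lamA * yA + g * inA) * dt + cs2 * np.random.normal()
                yB += (lamB * yB + g * inB) * dt + cs2 * np.random.normal()
                if t == n_view - 1:
                    ybarA = yA / n_view
                    ybarB = yB / n_view
            else:
                yA += lamA * yA * dt + ybarA + cs2 * np.random.normal()
                yB += lamB * yB * dt + ybarB + cs2 * np.random.normal()
            u = yA - yB
            if u >= bu[t]:
                ch = 1
                st = t + 1
                to = False
                break
            if u <= -bu[t]:
                ch = -1
                st = t + 1
                to = False
                break
            pu = _bridge_up(bu[t] - uprev, bu[t] - u, var)
            pl = _bridge_up(uprev + bu[t], u + bu[t], var)
            if (pu > 0.0 or pl > 0.0) and np.random.random() < pu + pl:
                ch = 1 if np.random.random() < pu / (pu + pl) else -1
                st = t + 1
                to = False
                break
        if to:
            ch = _finish(yA - yB, np.random.random())
        out_choice[i] = ch
        out_steps[i] = st
        out_to[i] = to
        prev = float(ch)
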