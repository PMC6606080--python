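"""Dynamic-protocol simulators: time-varying input DDM and leaky accumulators.

In the dynamic protocol the accumulator is driven by a per-trial evidence
time series during the viewing period (150 Euler steps of 5 ms for a 750 ms
stimulus); after stimulus offset the deterministic drive becomes the average
evidence accumulated per viewing step, and the process can run for at most
300 further steps before timing out.  RT is measured from stimulus onset
plus non-decision time.

Three leaky-accumulator history biases are implemented: a starting-point
shift, an input (drift) shift, and a λ asymmetry between two racing
accumulators whose difference is the decision variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels, _noise
from .bounds import BoundSchedule, deviation_bounds
from .ddm import SimResult, SimulationError, bias_terms, _check_start, _crossing_rt, DT_DEFAULT
from .models import ModelSpec, ParamSet, SpecError, LAMBDA_SIGN_CONVENTIONS

N_POST_DEFAULT = 300
_CHUNK_ELEMENTS = 30_000_000


@dataclass
class EvidenceTraces:
    """Per-trial evidence time series (trials x samples), sampled every dt."""

    values: np.ndarray
    dt: float = DT_DEFAULT

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("evidence traces must be finite")

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]


def build_input_trace(samples, pre_trimmed: bool = False, dt: float = DT_DEFAULT) -> EvidenceTraces:
    """Turn raw 60 Hz evidence samples into model input traces.

    The raw stimulus yields 45 samples per 750 ms trial; the first 15
    (250 ms, the filter rise time) are discarded and the remaining 30 are
    expanded onto 150 samples by constant interpolation (each sample
    repeated 5x), giving a 750 ms series at the 5 ms Euler step.

    Parameters
    ----------
    samples
        (n_trials, 45) raw samples, or (n_trials, 30) with
        ``pre_trimmed=True``.  A single 1-D trial is also accepted.
    """
    arr = np.atleast_2d(np.asarray(samples, dtype=float))
    want = 30 if pre_trimmed else 45
    if arr.shape[1] != want:
        bad = arr.shape[1]
        raise ValueError(
            f"expected {want} samples per trial (got {bad}); "
            "pass pre_trimmed=True for 30-sample input"
        )
    if not pre_trimmed:
        arr = arr[:, 15:]
    return EvidenceTraces(np.repeat(arr, 5, axis=1), dt=dt)


def write_traces_csv(traces: EvidenceTraces, path, trials=None) -> None:
    """One row per trial: subject,session,trial,sample_000..sample_NNN."""
    import pandas as pd

    n_t, n_s = traces.values.shape
    cols = {f"sample_{i:03d}": traces.values[:, i] for i in range(n_s)}
    meta = {}
    if trials is not None:
        meta = {k: trials[k].to_numpy() for k in ("subject", "session", "trial")}
    else:
        meta = {"subject": np.zeros(n_t, dtype=int), "session": np.zeros(n_t, dtype=int),
                "trial": np.arange(n_t)}
    pd.DataFrame({**meta, **cols}).to_csv(path, index=False)


def read_traces_csv(path, dt: float = DT_DEFAULT) -> EvidenceTraces:
    import pandas as pd

    df = pd.read_csv(path)
    sample_cols = sorted(c for c in df.columns if c.startswith("sample_"))
    if not sample_cols:
        raise ValueError("no sample_* columns found")
    return EvidenceTraces(df[sample_cols].to_numpy(dtype=float), dt=dt)


def write_traces_hdf5(traces_by_subject: dict, path, dt: float = DT_DEFAULT) -> None:
    """HDF5 container: one (trials x samples) array per subject + dt attr."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["dt"] = dt
        for subject, tr in traces_by_subject.items():
            vals = tr.values if isinstance(tr, EvidenceTraces) else np.asarray(tr)
            f.create_dataset(str(subject), data=vals)


def read_traces_hdf5(path) -> dict:
    import h5py

    out = {}
    with h5py.File(path, "r") as f:
        dt = float(f.attrs["dt"])
        for key in f:
            out[key] = EvidenceTraces(f[key][()], dt=dt)
    return out


def _as_trace_matrix(traces) -> np.ndarray:
    if isinstance(traces, EvidenceTraces):
        return traces.values
    return np.atleast_2d(np.asarray(traces, dtype=float))


def _run_scalar(M, prev, n_rep, seed, params, lam, zb, vb, ramp, schedule, dt, n_post):
    n_trials, n_view = M.shape
    n_steps = n_view + n_post
    bu, bl = deviation_bounds(schedule, n_steps, dt)
    n = n_trials * n_rep
    trial_idx = np.repeat(np.arange(n_trials), n_rep)
    prev_t = prev[trial_idx]
    choice = np.empty(n, dtype=np.int64)
    steps = np.empty(n, dtype=np.int64)
    timed_out = np.empty(n, dtype=np.bool_)
    cs = params.noise_c * np.sqrt(dt)
    chunk = max(1, _CHUNK_ELEMENTS // n_steps)
    for lo in range(0, n, chunk):
        hi = min(n, lo + chunk)
        sl = slice(lo, hi)
        nn = hi - lo
        bank = _noise.noise_bank("scalar", seed, lo, nn, n_steps)
        u0 = params.sz * bank["u"] + zb * prev_t[sl]
        _kernels.scalar_dyn_grid(
            u0, lam, params.g, vb * prev_t[sl], ramp * prev_t[sl],
            trial_idx[sl], M, dt, n_view, bu, bl, cs, bank["noise"], bank["tie"],
            np.uint64(int(seed) % (2**62) + lo),
            choice[sl], steps[sl], timed_out[sl],
        )
    rt = _crossing_rt(params.ter, steps, timed_out, dt)
    return SimResult(choice, rt, timed_out, trial_idx, prev_t, n, seed)


def simulate_dynamic_ddm(
    spec: ModelSpec,
    params: ParamSet,
    traces,
    prev,
    n_rep: int = 1,
    seed: int = 0,
    dt: float = DT_DEFAULT,
    n_post: int = N_POST_DEFAULT,
) -> SimResult:
    """Simulate the dynamic-protocol DDM (time-varying input, no leak)."""
    if spec.family != "ddm_dynamic":
        raise SpecError(f"simulate_dynamic_ddm requires family ddm_dynamic, got {spec.family}")
    M = _as_trace_matrix(traces)
    prev = np.asarray(prev, dtype=float).ravel()
    if M.shape[0] != prev.size:
        raise ValueError(f"trace/trial count mismatch: {M.shape[0]} traces vs {prev.size} prev values")
    zb, vb, ramp = bias_terms(spec, params)
    _check_start(params, zb)
    schedule = BoundSchedule(spec.bounds, params.a, params.c_collapse, "midpoint")
    return _run_scalar(M, prev, n_rep, seed, params, 0.0, zb, vb, ramp, schedule, dt, n_post)


def effective_lambda(params: ParamSet, convention: str) -> tuple[float, float]:
    """Resolve (λ, λ_bias) under the chosen sign convention.

    ``positive_excites`` reads the accumulation term λ·y literally
    (positive λ is self-excitatory); ``negative_excites`` flips the sign,
    for the reporting convention in which negative values denote
    self-excitation.
    """
    if convention not in LAMBDA_SIGN_CONVENTIONS:
        raise ValueError(f"unknown lambda_sign_convention {convention!r}")
    s = 1.0 if convention == "positive_excites" else -1.0
    return s * params.lam, s * params.lam_bias


def simulate_leaky(
    spec: ModelSpec,
    params: ParamSet,
    traces,
    prev,
    n_rep: int = 1,
    seed: int = 0,
    dt: float = DT_DEFAULT,
    n_post: int = N_POST_DEFAULT,
    engine: str | None = None,
    lambda_sign_convention: str = "positive_excites",
) -> SimResult:
    """Simulate a leaky accumulator variant.

    ``engine="scalar"`` evolves the scalar difference variable (starting
    point and input biases); ``engine="dual"`` evolves two racing
    accumulators fed by the rectified input halves, which is required for
    the λ-bias variant and is also how the simulation-study generators are
    set up.  Default: dual for lambda_bias, scalar otherwise.
    """
    if spec.family != "leaky":
        raise SpecError(f"simulate_leaky requires family leaky, got {spec.family}")
    if spec.bias_type not in ("starting_point", "input_bias", "lambda_bias"):
        raise SpecError(f"leaky family does not define bias_type {spec.bias_type!r}")
    if engine is None:
        engine = "dual" if spec.bias_type == "lambda_bias" else "scalar"
    if engine not in ("scalar", "dual"):
        raise ValueError(f"unknown engine {engine!r}")
    if spec.bias_type == "lambda_bias" and engine == "scalar":
        raise SpecError("lambda_bias requires the two-accumulator (dual) dynamics")

    M = _as_trace_matrix(traces)
    prev = np.asarray(prev, dtype=float).ravel()
    if M.shape[0] != prev.size:
        raise ValueError(f"trace/trial count mismatch: {M.shape[0]} traces vs {prev.size} prev values")
    lam, lam_bias = effective_lambda(params, lambda_sign_convention)
    zb, vb, _ = bias_terms(spec, params)

    if engine == "scalar":
        _check_start(params, zb)
        schedule = BoundSchedule(spec.bounds, params.a, params.c_collapse, "midpoint")
        return _run_scalar(M, prev, n_rep, seed, params, lam, zb, vb, 0.0, schedule, dt, n_post)

    # dual engine: decision variable yA - yB, symmetric bounds ±a
    schedule = BoundSchedule(spec.bounds, params.a, params.c_collapse, "zero")
    n_trials, n_view = M.shape
    n_steps = n_view + n_post
    bu, _ = deviation_bounds(schedule, n_steps, dt)
    n = n_trials * n_rep
    trial_idx = np.repeat(np.arange(n_trials), n_rep)
    prev_t = prev[trial_idx]
    choice = np.empty(n, dtype=np.int64)
    steps = np.empty(n, dtype=np.int64)
    timed_out = np.empty(n, dtype=np.bool_)
    cs2 = params.noise_c * np.sqrt(dt) / np.sqrt(2.0)
    lamA = lam + np.where(prev_t > 0, lam_bias, 0.0)
    lamB = lam + np.where(prev_t < 0, lam_bias, 0.0)
    chunk = max(1, _CHUNK_ELEMENTS // (2 * n_steps))
    for lo in range(0, n, chunk):
        hi = min(n, lo + chunk)
        sl = slice(lo, hi)
        nn = hi - lo
        bank = _noise.noise_bank("dual", seed, lo, nn, n_steps)
        uA0 = params.sz * bank["u"] + zb * prev_t[sl]
        _kernels.dual_grid(
            uA0, lamA[sl], lamB[sl], params.g, vb * prev_t[sl],
            trial_idx[sl], M, dt, n_view, bu, cs2, bank["noise"], bank["noise_b"],
            bank["tie"],
            np.uint64(int(seed) % (2**62) + lo),
            choice[sl], steps[sl], timed_out[sl],
        )
    rt = _crossing_rt(params.ter, steps, timed_out, dt)
    return SimResult(choice, rt, timed_out, trial_idx, prev_t, n, seed)
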