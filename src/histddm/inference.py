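"""Across-observer inference.

Rank correlations between individual bias measures, Steiger's test for
comparing two dependent correlations that share a variable, default Bayes
factors for correlations (multiplied across datasets to aggregate
evidence), exponential fits to multi-lag history kernels, and a Markov
correction for repetition probability at longer lags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

import pingouin


@dataclass
class CorrelationReport:
    rho: float
    n: int
    p: float
    ci95: tuple[float, float]
    bf10: float | None = None


def spearman(x, y) -> CorrelationReport:
    """Spearman rank correlation with Fisher-transform CI.

    Average ranks for ties; the p-value is the standard large-sample
    approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    n = x.size
    if n < 4:
        raise ValueError(f"need n >= 4 observers, got {n}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("correlation undefined for a constant input vector")
    rho, p = stats.spearmanr(x, y)
    rho = float(rho)
    if abs(rho) < 1.0:
        z = np.arctanh(rho)
        hw = 1.959963984540054 / np.sqrt(n - 3)
        ci = (float(np.tanh(z - hw)), float(np.tanh(z + hw)))
    else:
        ci = (rho, rho)
    return CorrelationReport(rho, n, float(p), ci)


def steiger_compare(r12: float, r13: float, r23: float, n: int) -> tuple[float, float]:
    """Two-sided test of H0: ρ12 = ρ13 for correlations sharing variable 1.

    Dependent-correlation z statistic on Fisher-transformed coefficients,
    accounting for the overlap through r23.  Returns (z, p).
    """
    for name, r in (("r12", r12), ("r13", r13), ("r23", r23)):
        if not -1 < r < 1:
            raise ValueError(f"{name} must lie strictly inside (-1, 1), got {r}")
    if n <= 3:
        raise ValueError(f"need n > 3, got {n}")
    z12 = np.arctanh(r12)
    z13 = np.arctanh(r13)
    rm = (r12 + r13) / 2.0
    f = min((1.0 - r23) / (2.0 * (1.0 - rm**2)), 1.0)
    h = (1.0 - f * rm**2) / (1.0 - rm**2)
    z = (z12 - z13) * np.sqrt((n - 3) / (2.0 * (1.0 - r23) * h))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def bf_correlation(rho: float, n: int) -> float:
    """Default Bayes factor BF10 for a correlation coefficient.

    Exact integral under a uniform prior on the coefficient (stretched-beta
    with κ = 1); BF10 > 1 favors a nonzero correlation.  Values < 1/10 or
    > 10 are conventionally read as substantial evidence.
    """
    if n <= 3:
        raise ValueError(f"need n > 3, got {n}")
    if not -1 <= rho <= 1:
        raise ValueError(f"rho must lie in [-1, 1], got {rho}")
    bf = float(pingouin.bayesfactor_pearson(rho, n, method="ly", kappa=1.0))
    if not np.isfinite(bf):
        raise ArithmeticError(f"Bayes factor integral did not converge (r={rho}, n={n})")
    return bf


def combine_bf(bfs) -> float:
    """Product of per-dataset Bayes factors (evidence aggregation)."""
    bfs = list(bfs)
    if not bfs:
        raise ValueError("need at least one Bayes factor")
    if any(b <= 0 for b in bfs):
        raise ValueError("Bayes factors must be > 0")
    return float(np.prod(bfs))


@dataclass
class ExpKernelFit:
    amplitude: float
    tau: float
    at_bound: bool  # tau pinned at the box bound: non-decaying kernel


def fit_exponential_kernel(weights, lags=None, tau_max: float = 100.0) -> ExpKernelFit:
    """Least-squares fit of V_t = A * exp(-t / τ) to per-lag kernel weights."""
    weights = np.asarray(weights, dtype=float)
    lags = np.arange(1, weights.size + 1, dtype=float) if lags is None else np.asarray(lags, dtype=float)
    if weights.size < 3:
        raise ValueError("need at least 3 lags")
    if np.any(lags < 1):
        raise ValueError("lags must be positive integers")

    def model(t, A, tau):
        return A * np.exp(-t / tau)

    a0 = weights[0] if weights[0] != 0 else (np.max(np.abs(weights)) or 1.0)
    try:
        popt, _ = optimize.curve_fit(
            model, lags, weights, p0=[a0, 2.0],
            bounds=([-np.inf, 1e-6], [np.inf, tau_max]), maxfev=10000,
        )
    except RuntimeError as e:
        raise ArithmeticError(f"exponential kernel fit failed: {e}") from e
    A, tau = float(popt[0]), float(popt[1])
    return ExpKernelFit(A, tau, at_bound=tau >= tau_max * (1 - 1e-6))


@dataclass
class CorrectedRepeat:
    lag: int
    raw: float
    expected: float
    corrected: float
    method: str = "markov_lag1_correction"


def p_repeat_at_lag(trials: pd.DataFrame, lag: int) -> float:
    """Raw probability that the choice matches the choice ``lag`` back."""
    from .data_model import derive_history_columns

    if lag < 1:
        raise ValueError("lag must be >= 1")
    d = derive_history_columns(trials, lag)
    col = d[f"choice_lag{lag}"]
    sel = col.notna()
    if sel.sum() == 0:
        raise ValueError(f"no trials with {lag} preceding trials in session")
    return float((d.loc[sel, "choice"] == col[sel]).mean())


def corrected_p_repeat_at_lag(trials: pd.DataFrame, lag: int) -> CorrectedRepeat:
    """Lag-k repetition probability minus its Markov-chain expectation.

    The expectation iterates the observer's lag-1 repetition probability p1
    as a two-state chain: expected_k = 0.5 + 0.5 * (2 p1 - 1)^k.  This
    removes the repetition trivially implied at longer lags by the lag-1
    bias alone; the correction method is reported alongside the value.
    """
    if lag < 2:
        raise ValueError("corrected repetition is defined for lag >= 2")
    p1 = p_repeat_at_lag(trials, 1)
    raw = p_repeat_at_lag(trials, lag)
    expected = markov_expected_repeat(p1, lag)
    return CorrectedRepeat(lag, raw, expected, raw - expected)


def markov_expected_repeat(p1: float, lag: int) -> float:
    """Lag-k repetition implied by iterating lag-1 repetition p1."""
    return 0.5 + 0.5 * (2.0 * p1 - 1.0) ** lag
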