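"""Model-free behavioral measures.

Sensitivity (signal-detection d'), choice-repetition probability,
conditional bias functions (the RT-resolved diagnostic that separates
starting-point from accumulation biases), outcome-dependent strategy
classification, and psychophysical kernels from evidence traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_model import history_valid

CBF_QUANTILE_LABELS = (0.1, 0.3, 0.5, 0.7, 0.9)


def dprime(hits: float, false_alarms: float) -> float:
    """Signal-detection sensitivity Φ⁻¹(H) − Φ⁻¹(FA).

    Both proportions are clamped into [0.001, 0.999] so that d' remains
    finite under (near-)perfect performance.  For 2AFC/2IFC tasks one of
    the two stimulus categories is arbitrarily designated "signal absent".
    """
    for name, v in (("hits", hits), ("false_alarms", false_alarms)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    h = min(max(hits, 0.001), 0.999)
    fa = min(max(false_alarms, 0.001), 0.999)
    return float(norm.ppf(h) - norm.ppf(fa))


def dprime_from_trials(trials: pd.DataFrame, signal_category: int = 1) -> float:
    """d' of a trial table, treating ``signal_category`` as signal present."""
    stim = trials["stimulus"].to_numpy()
    choice = trials["choice"].to_numpy()
    sig = stim == signal_category
    if sig.sum() == 0 or (~sig).sum() == 0:
        raise ValueError("both stimulus categories must be present")
    h = (choice[sig] == signal_category).mean()
    fa = (choice[~sig] == signal_category).mean()
    return dprime(h, fa)


def p_repeat(trials: pd.DataFrame) -> float:
    """Probability of repeating the previous choice (0.5 = no bias).

    Uses history-valid trials only (first trial of each session excluded).
    """
    hv = history_valid(trials)
    if len(hv) == 0:
        raise ValueError("no valid choice transitions (need >= 2 trials in a session)")
    return float((hv["choice"] == hv["prev_choice"]).mean())


def repetition_by_outcome(trials: pd.DataFrame) -> tuple[float, float]:
    """(P(repeat | previous correct), P(repeat | previous error))."""
    hv = history_valid(trials)
    rep = hv["choice"] == hv["prev_choice"]
    prev_ok = hv["prev_correct"].astype(bool)
    if prev_ok.sum() == 0 or (~prev_ok).sum() == 0:
        raise ValueError("need both previous-correct and previous-error trials")
    return float(rep[prev_ok].mean()), float(rep[~prev_ok].mean())


@dataclass
class CBF:
    """Conditional bias function: fraction of bias-consistent choices per
    RT quintile bin (bins labeled by their representative quantiles)."""

    quantile_labels: tuple
    fraction_biased: np.ndarray
    n_per_bin: np.ndarray
    bias_direction: str  # {repeat, alternate}
    tie_flag: bool = False


def conditional_bias_function(trials: pd.DataFrame) -> CBF:
    """Compute the conditional bias function of one observer.

    The observer is classified as a repeater (P(repeat) > 0.5) or
    alternator; each history-valid trial is 'biased' if its choice goes in
    the observer's bias direction.  Trials are split into five equal-mass RT
    bins (quintiles) and the biased fraction is computed per bin.  A
    starting-point bias concentrates biased choices in the fastest bin; an
    accumulation bias sustains them across all bins, slowest included.
    """
    hv = history_valid(trials)
    if len(hv) < 5:
        raise ValueError("need at least 5 history-valid trials")
    pr = float((hv["choice"] == hv["prev_choice"]).mean())
    tie = pr == 0.5
    if tie:
        warnings.warn("P(repeat) exactly 0.5; bias direction assigned as 'repeat'")
    direction = "repeat" if pr >= 0.5 else "alternate"
    rep = (hv["choice"] == hv["prev_choice"]).to_numpy()
    biased = rep if direction == "repeat" else ~rep
    rt = hv["rt"].to_numpy(dtype=float)
    edges = np.quantile(rt, [0.2, 0.4, 0.6, 0.8])
    bins = np.searchsorted(edges, rt, side="left")
    frac = np.empty(5)
    n = np.empty(5, dtype=int)
    for b in range(5):
        sel = bins == b
        n[b] = sel.sum()
        frac[b] = biased[sel].mean() if n[b] else np.nan
    return CBF(CBF_QUANTILE_LABELS, frac, n, direction, tie)


def classify_strategy(p_rep_after_correct: float, p_rep_after_error: float) -> str:
    """Quadrant rule on outcome-conditioned repetition probabilities.

    stay / switch when both probabilities fall on the same side of 0.5;
    win_stay_lose_switch / win_switch_lose_stay otherwise.  A probability
    exactly at 0.5 is resolved toward the stay/switch axis (with a
    warning), never silently.
    """
    for name, v in (("p_rep_after_correct", p_rep_after_correct),
                    ("p_rep_after_error", p_rep_after_error)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if p_rep_after_correct == 0.5 or p_rep_after_error == 0.5:
        warnings.warn("repetition probability exactly 0.5; tie resolved toward stay/switch axis")
    c_hi = p_rep_after_correct >= 0.5
    e_hi = p_rep_after_error >= 0.5
    if c_hi and e_hi:
        return "stay"
    if not c_hi and not e_hi:
        return "switch"
    if c_hi:
        return "win_stay_lose_switch"
    return "win_switch_lose_stay"


def psychophysical_kernel(
    traces,
    trials: pd.DataFrame,
    exclude_strength: float | None = 81.0,
) -> np.ndarray:
    """Choice-conditioned excess evidence per timepoint.

    Within each stimulus identity (signed direction x strength, optionally
    excluding the easiest level), the mean trace of +1 choices minus the
    mean trace of -1 choices; identity-wise kernels are averaged into one
    series.  Positive early values with near-zero late values indicate
    primacy (early evidence drives choices).
    """
    M = traces.values if hasattr(traces, "values") and not isinstance(traces, np.ndarray) else np.asarray(traces)
    M = np.atleast_2d(M)
    if M.shape[0] != len(trials):
        raise ValueError("traces and trials must be aligned")
    choice = trials["choice"].to_numpy()
    strength = trials["strength"].to_numpy(dtype=float)
    kernels = []
    for s in np.unique(strength):
        if exclude_strength is not None and abs(abs(s) - exclude_strength) < 1e-12:
            continue
        sel = strength == s
        up = sel & (choice == 1)
        dn = sel & (choice == -1)
        if up.sum() == 0 or dn.sum() == 0:
            warnings.warn(f"stimulus identity {s}: only one choice present; skipped")
            continue
        kernels.append(M[up].mean(axis=0) - M[dn].mean(axis=0))
    if not kernels:
        raise ValueError("no stimulus identity had both choices")
    return np.mean(kernels, axis=0)
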