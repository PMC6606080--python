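"""Trial-level data structures and delimited-text I/O.

The universal container is a pandas DataFrame with one row per trial and the
canonical columns

    subject, session, trial, stimulus, strength, choice, rt, correct, feedback

plus the derived history columns ``prev_choice`` / ``prev_correct`` (NaN on
the first trial of a session).  Stimuli and choices are coded as signed
categories {-1, +1}; response time ``rt`` is in seconds, strictly positive.
All downstream code (simulators, binning, behavioral statistics) consumes
this frame, so simulated and empirical data flow through the same pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("subject", "session", "trial", "stimulus", "choice", "rt")
CANONICAL_COLUMNS = (
    "subject", "session", "trial", "stimulus", "strength", "choice",
    "rt", "correct", "feedback",
)


class SchemaError(ValueError):
    """A required column is missing or unresolvable."""


class ValidationError(ValueError):
    """Rows violate a trial-table invariant; the message names them."""


def _remap_binary(values: pd.Series, name: str) -> pd.Series:
    """Accept {0,1} coding for signed categories and remap to {-1,+1}."""
    vals = set(pd.unique(values.dropna()))
    if vals <= {0, 1}:
        return values.replace({0: -1}).astype(float)
    if not vals <= {-1, 1}:
        raise ValidationError(f"column {name!r} must be coded -1/+1 (or 0/1), found {sorted(vals)}")
    return values.astype(float)


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table and (re)derive the history columns.

    Returns a copy sorted by subject/session/trial with ``prev_choice`` and
    ``prev_correct`` computed within each (subject, session) block and set to
    NaN across session boundaries.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    out = df.copy()
    if "strength" not in out.columns:
        out["strength"] = out["stimulus"].astype(float)
    out["stimulus"] = _remap_binary(out["stimulus"], "stimulus")
    out["choice"] = _remap_binary(out["choice"], "choice")

    bad_rt = np.flatnonzero(~(out["rt"].to_numpy(dtype=float) > 0))
    if bad_rt.size:
        raise ValidationError(f"rt must be > 0; offending row index(es): {bad_rt.tolist()[:20]}")

    if "correct" not in out.columns:
        out["correct"] = out["stimulus"] == out["choice"]
    out["correct"] = out["correct"].astype(bool)
    nz = out["strength"].to_numpy(dtype=float) != 0
    mismatch = np.flatnonzero(
        nz & (out["correct"].to_numpy() != (out["stimulus"].to_numpy() == out["choice"].to_numpy()))
    )
    if mismatch.size:
        raise ValidationError(
            f"correct must equal (stimulus == choice) when strength != 0; rows: {mismatch.tolist()[:20]}"
        )
    # Two of the six study tasks showed no outcome feedback; absent column
    # means feedback was not shown.
    if "feedback" not in out.columns:
        out["feedback"] = False
    out["feedback"] = out["feedback"].astype(bool)

    out = out.sort_values(["subject", "session", "trial"], kind="stable").reset_index(drop=True)
    grp = out.groupby(["subject", "session"], sort=False)
    out["prev_choice"] = grp["choice"].shift(1)
    out["prev_correct"] = grp["correct"].shift(1)
    return out


def read_trials(path, dialect: dict | None = None, rt_unit: str = "s") -> pd.DataFrame:
    """Read a delimited trial file into a validated trial table.

    Parameters
    ----------
    path
        CSV file with a header row.
    dialect
        Optional mapping from canonical column names to the file's column
        names, e.g. ``{"rt": "reaction_time"}``.
    rt_unit
        ``"s"`` or ``"ms"``; times are normalised to seconds.
    """
    if rt_unit not in ("s", "ms"):
        raise ValueError(f"rt_unit must be 's' or 'ms', got {rt_unit!r}")
    raw = pd.read_csv(path)
    if dialect:
        raw = raw.rename(columns={v: k for k, v in dialect.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing} (after dialect mapping)")
    if rt_unit == "ms":
        raw["rt"] = raw["rt"].astype(float) / 1000.0
    return validate_trials(raw)


def write_trials(df: pd.DataFrame, path) -> None:
    """Write the canonical columns of a trial table to CSV."""
    cols = [c for c in CANONICAL_COLUMNS if c in df.columns]
    df.to_csv(path, index=False, columns=cols)


def derive_history_columns(trials: pd.DataFrame, lag: int) -> pd.DataFrame:
    """Add ``choice_lag{lag}`` / ``stimulus_lag{lag}`` columns.

    Values are NaN wherever the lag would cross a session boundary.  lag=1
    reproduces ``prev_choice``.
    """
    if lag < 1:
        raise ValueError(f"lag must be >= 1, got {lag}")
    out = trials.copy()
    grp = out.groupby(["subject", "session"], sort=False)
    out[f"choice_lag{lag}"] = grp["choice"].shift(lag)
    out[f"stimulus_lag{lag}"] = grp["stimulus"].shift(lag)
    return out


def history_valid(trials: pd.DataFrame) -> pd.DataFrame:
    """Rows with a defined previous choice (drops first trial of each session)."""
    return trials[trials["prev_choice"].notna()]
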