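"""Decision-bound schedules (static and hyperbolically collapsing)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BoundSchedule:
    """Time course of the two decision bounds.

    ``midpoint`` mode is used by all single-accumulator models (decision
    variable between 0 and a, neutral point a/2): the bounds collapse
    hyperbolically toward the midpoint and are clamped at a/2.  ``zero``
    mode is used by the two-accumulator race (decision variable yA - yB,
    neutral point 0, symmetric bounds ±a): the upper bound collapses toward
    an asymptote of 0.
    """

    kind: str = "static"                # {static, collapsing}
    a: float = 1.0
    c_collapse: float = 3.0             # seconds
    asymptote_mode: str = "midpoint"    # {midpoint, zero}

    def __post_init__(self) -> None:
        if self.kind not in ("static", "collapsing"):
            raise ValueError(f"unknown bound kind {self.kind!r}")
        if self.asymptote_mode not in ("midpoint", "zero"):
            raise ValueError(f"unknown asymptote_mode {self.asymptote_mode!r}")
        if not self.a > 0:
            raise ValueError("bound parameter a must be > 0")
        if self.kind == "collapsing" and not self.c_collapse > 0:
            raise ValueError("c_collapse must be > 0 for collapsing bounds")


def bounds_at(schedule: BoundSchedule, t):
    """Bound values (b_up, b_down) at time ``t`` (seconds; scalar or array).

    midpoint mode: b_up = clamp(a - a*t/(t+c), a/2, a),
                   b_down = clamp(a*t/(t+c), 0, a/2).
    zero mode:     b_up = clamp(a - a*t/(t+c), 0, a), b_down = -b_up.
    """
    t = np.asarray(t, dtype=float)
    a = schedule.a
    if schedule.kind == "static":
        b_up = np.full_like(t, a)
    else:
        b_up = a - a * t / (t + schedule.c_collapse)
    if schedule.asymptote_mode == "midpoint":
        b_up = np.clip(b_up, a / 2, a)
        b_down = a - b_up
    else:
        b_up = np.clip(b_up, 0.0, a)
        b_down = -b_up
    return b_up, b_down


def deviation_bounds(schedule: BoundSchedule, n_steps: int, dt: float):
    """Per-step bound arrays in deviation coordinates (u = y - neutral).

    The bound is evaluated at the *end* of each Euler step, i.e. at times
    dt, 2*dt, ..., n_steps*dt, matching when crossings are checked.
    """
    t = (np.arange(n_steps) + 1) * dt
    b_up, b_down = bounds_at(schedule, t)
    if schedule.asymptote_mode == "midpoint":
        neutral = schedule.a / 2
        return b_up - neutral, b_down - neutral
    return b_up, b_down
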