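"""Model-variant taxonomy and parameter containers.

A :class:`ModelSpec` names one member of the bounded-accumulation model zoo:
the accumulator family (classic DDM driven by a per-trial scalar drift,
dynamic DDM driven by a time-varying evidence trace, or leaky accumulator),
the history-bias mechanism attached to it, and the bound regime.  A
:class:`ParamSet` carries the numeric parameters; which of them are free is a
property of the spec, not of the container.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Iterable

FAMILIES = ("ddm_default", "ddm_dynamic", "leaky")
BIAS_TYPES = (
    "none",
    "starting_point",
    "drift_bias",
    "hybrid",
    "ramp",
    "hybrid_ramp",
    "input_bias",
    "lambda_bias",
)
BOUND_KINDS = ("static", "collapsing")

#: λ-sign conventions. ``positive_excites`` reads the accumulation term
#: dy = λ·y·dt literally (λ>0 self-excitatory/unstable, λ<0 leaky).
#: ``negative_excites`` flips the sign, matching the reporting convention
#: in which *negative* λ values denote self-excitation.
LAMBDA_SIGN_CONVENTIONS = ("positive_excites", "negative_excites")


class SpecError(ValueError):
    """An inconsistent model specification."""


@dataclass(frozen=True)
class ModelSpec:
    """One bounded-accumulation model variant.

    Parameters
    ----------
    family
        ``ddm_default`` (scalar per-trial drift, accumulation after stimulus
        offset), ``ddm_dynamic`` (time-varying input during viewing, then
        continuation at the accumulated average), or ``leaky`` (accumulation
        with an effective-leak term λ·y).
    bias_type
        History-bias mechanism keyed to the previous choice.
    bounds
        ``static`` or hyperbolically ``collapsing`` decision bounds.
    """

    family: str = "ddm_default"
    bias_type: str = "none"
    bounds: str = "static"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise SpecError(f"unknown family {self.family!r}")
        if self.bias_type not in BIAS_TYPES:
            raise SpecError(f"unknown bias_type {self.bias_type!r}")
        if self.bounds not in BOUND_KINDS:
            raise SpecError(f"unknown bounds {self.bounds!r}")
        if self.bias_type in ("ramp", "hybrid_ramp") and self.family == "leaky":
            raise SpecError("ramp biases are only defined for DDM families")
        if self.bias_type in ("input_bias", "lambda_bias") and self.family != "leaky":
            raise SpecError(f"{self.bias_type} requires the leaky family")

    @property
    def tag(self) -> str:
        return f"{self.family}:{self.bias_type}:{self.bounds}"

    def free_params(self) -> tuple[str, ...]:
        """Names of the free parameters this variant is fitted with."""
        if self.family == "ddm_default":
            base = ["a", "g", "ter", "sv", "sz"]
        elif self.family == "ddm_dynamic":
            base = ["a", "g", "ter", "sz"]
        else:
            base = ["a", "lam", "g", "ter", "sz"]
        if self.bounds == "collapsing":
            base.append("c_collapse")
        extra = {
            "none": [],
            "starting_point": ["z_bias"],
            "drift_bias": ["v_bias"],
            "hybrid": ["z_bias", "v_bias"],
            "ramp": ["s_ramp"],
            "hybrid_ramp": ["s_constant", "s_ramp"],
            "input_bias": ["v_bias"],
            "lambda_bias": ["lam_bias"],
        }[self.bias_type]
        return tuple(base + extra)


@dataclass(frozen=True)
class ParamSet:
    """Numeric parameters of a bounded-accumulation model.

    All times are in seconds; the diffusion noise SD ``noise_c`` is fixed at 1
    so that the input-scaling parameter ``g`` sets the signal-to-noise ratio.

    Attributes
    ----------
    a : bound separation (decision-variable units)
    g : input scaling (1/evidence units)
    ter : non-decision time, s
    sv : SD of the per-trial effective drift (drift-rate variability)
    sz : half-width of the uniform starting-point jitter
    z_bias : additive starting-point shift, applied as ``z_bias * prev``
    v_bias : additive drift (or input) shift, applied as ``v_bias * prev``
    s_ramp : slope of a linearly ramping drift bias, 1/s
    s_constant : constant component of the hybrid-ramp drift bias
    lam : effective leak λ, 1/s (see `lambda_sign_convention` in simulators)
    lam_bias : additive λ asymmetry between the two accumulators, 1/s
    c_collapse : hyperbolic bound-collapse time constant, s
    noise_c : diffusion noise SD (fixed at 1 unless explicitly overridden)
    """

    a: float = 1.0
    g: float = 1.0
    ter: float = 0.1
    sv: float = 0.0
    sz: float = 0.0
    z_bias: float = 0.0
    v_bias: float = 0.0
    s_ramp: float = 0.0
    s_constant: float = 0.0
    lam: float = 0.0
    lam_bias: float = 0.0
    c_collapse: float = 3.0
    noise_c: float = 1.0

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise SpecError(f"bound separation a must be > 0, got {self.a}")
        if self.ter < 0:
            raise SpecError(f"non-decision time must be >= 0, got {self.ter}")
        if self.sv < 0:
            raise SpecError(f"sv must be >= 0, got {self.sv}")
        if not (0 <= self.sz < self.a / 2):
            raise SpecError(f"sz must lie in [0, a/2), got sz={self.sz}, a={self.a}")
        if not self.c_collapse > 0:
            raise SpecError(f"c_collapse must be > 0, got {self.c_collapse}")

    def replace(self, **kw) -> "ParamSet":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_values(cls, names: Iterable[str], values: Iterable[float], **fixed) -> "ParamSet":
        kw = dict(fixed)
        kw.update(dict(zip(names, values, strict=True)))
        return cls(**kw)


# Box bounds used for the uniform random starting sets and the constrained
# simplex search.  sz and z_bias are searched as fractions of a (so the
# sz < a/2 invariant holds throughout the search) and converted back when a
# ParamSet is materialised.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "a": (0.3, 3.0),
    "g": (0.05, 10.0),
    "ter": (0.0, 0.5),
    "sv": (0.0, 2.0),
    "sz_frac": (0.0, 0.45),        # sz = sz_frac * a
    "z_bias_frac": (-0.4, 0.4),    # z_bias = z_bias_frac * a
    "v_bias": (-2.0, 2.0),
    "s_constant": (-2.0, 2.0),
    "s_ramp": (-5.0, 5.0),
    "lam": (-10.0, 10.0),
    "lam_bias": (-5.0, 5.0),
    "c_collapse": (0.01, 10.0),
}

_FRAC_OF_A = {"sz": "sz_frac", "z_bias": "z_bias_frac"}


def search_names(spec: ModelSpec) -> tuple[str, ...]:
    """Optimizer-space parameter names (fractional sz / z_bias)."""
    return tuple(_FRAC_OF_A.get(n, n) for n in spec.free_params())


def params_to_vector(spec: ModelSpec, params: ParamSet):
    """Map a ParamSet to the optimizer-space vector (fractional sz/z_bias)."""
    out = []
    for name in search_names(spec):
        if name in ("sz_frac", "z_bias_frac"):
            nat = "sz" if name == "sz_frac" else "z_bias"
            out.append(getattr(params, nat) / params.a)
        else:
            out.append(getattr(params, name))
    return out


def vector_to_params(spec: ModelSpec, x, fixed: dict | None = None) -> ParamSet:
    """Map an optimizer-space vector back to a :class:`ParamSet`."""
    names = search_names(spec)
    kw = dict(fixed or {})
    d = dict(zip(names, [float(v) for v in x], strict=True))
    a = d.get("a", kw.get("a", 1.0))
    for nat, frac in _FRAC_OF_A.items():
        if frac in d:
            d[nat] = d.pop(frac) * a
    kw.update(d)
    return ParamSet(**kw)
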