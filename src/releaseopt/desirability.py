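"""Derringer-Suich desirability functions and the composite objective.

Each response statistic is mapped to [0, 1] by an individual desirability:

* NTB (nominal-the-best): 0 outside [LSL, USL], 1 at the target T, rising as
  ((y-LSL)/(T-LSL))^r below T and falling as ((y-USL)/(T-USL))^s above.
* LTB (larger-the-better): 0 below the lowest acceptable value, 1 above the
  upper ideal, power-r ramp between.
* STB (smaller-the-better): mirror image of LTB.

The composite is the weighted geometric mean of all individual
desirabilities, exponent 1 / (sum of weights); a single zero-valued
positively weighted component annihilates the composite.  Computation goes
through sum(w * log d) with log 0 = -inf, so no epsilon flooring distorts
components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .rsm import ResponseSurface, evaluate_surface

__all__ = [
    "DesirabilitySpec",
    "Component",
    "CompositeSpec",
    "CompositeResult",
    "d_ntb",
    "d_ltb",
    "d_stb",
    "apply_desirability",
    "composite_desirability",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DesirabilitySpec:
    """Bounds and exponents of one individual desirability.

    NTB uses (lsl, target, usl); LTB uses (lower, upper_ideal) stored in
    (lsl, target); STB uses (lower_ideal, upper) stored in (target, usl).
    Exponents r (rising side) and s (falling side) default to linear ramps.
    """

    kind: str
    lsl: float | None = None
    target: float | None = None
    usl: float | None = None
    r: float = 1.0
    s: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("NTB", "LTB", "STB"):
            raise ValueError(f"unknown desirability kind {self.kind!r}")
        if self.r <= 0 or self.s <= 0:
            raise ValueError("desirability exponents must be positive")
        if self.kind == "NTB" and not (self.lsl < self.target < self.usl):
            raise ValueError("NTB requires lsl < target < usl")
        if self.kind == "LTB" and not (self.lsl < self.target):
            raise ValueError("LTB requires lower bound < upper ideal")
        if self.kind == "STB" and not (self.target < self.usl):
            raise ValueError("STB requires lower ideal < upper bound")


def d_ntb(y, lsl: float, target: float, usl: float, r: float = 1.0, s: float = 1.0):
    """Nominal-the-best desirability; accepts scalars or arrays."""
    y = np.asarray(y, dtype=float)
    rising = np.clip((y - lsl) / (target - lsl), 0.0, 1.0) ** r
    falling = np.clip((y - usl) / (target - usl), 0.0, 1.0) ** s
    d = np.where(y <= target, rising, falling)
    d = np.where((y <= lsl) | (y >= usl), 0.0, d)
    return float(d) if d.ndim == 0 else d


def d_ltb(y, lower: float, upper_ideal: float, r: float = 1.0):
    """Larger-the-better desirability; accepts scalars or arrays."""
    y = np.asarray(y, dtype=float)
    ramp = np.clip((y - lower) / (upper_ideal - lower), 0.0, 1.0) ** r
    d = np.where(y >= upper_ideal, 1.0, np.where(y <= lower, 0.0, ramp))
    return float(d) if d.ndim == 0 else d


def d_stb(y, lower_ideal: float, upper: float, r: float = 1.0):
    """Smaller-the-better desirability; accepts scalars or arrays."""
    y = np.asarray(y, dtype=float)
    ramp = np.clip((upper - y) / (upper - lower_ideal), 0.0, 1.0) ** r
    d = np.where(y <= lower_ideal, 1.0, np.where(y >= upper, 0.0, ramp))
    return float(d) if d.ndim == 0 else d


def apply_desirability(y, spec: DesirabilitySpec):
    if spec.kind == "NTB":
        return d_ntb(y, spec.lsl, spec.target, spec.usl, spec.r, spec.s)
    if spec.kind == "LTB":
        return d_ltb(y, spec.lsl, spec.target, spec.r)
    return d_stb(y, spec.target, spec.usl, spec.r)


@dataclass(frozen=True)
class Component:
    """One composite component: a surface, its desirability spec and weight.

    ``clamp_nonnegative`` floors the fitted value at 0 before the
    desirability map; used for variance and CV surfaces, whose OLS fits can
    dip below zero even though the statistic cannot.
    """

    surface: ResponseSurface
    spec: DesirabilitySpec
    weight: float = 1.0
    name: str = ""
    clamp_nonnegative: bool = False

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(f"component {self.name!r}: negative weight")


@dataclass
class CompositeSpec:
    """The full composite desirability specification."""

    components: list[Component] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.components and not any(c.weight > 0 for c in self.components):
            raise ValueError("all composite weights are zero")

    @property
    def total_weight(self) -> float:
        return sum(c.weight for c in self.components)


@dataclass(frozen=True)
class CompositeResult:
    value: float
    breakdown: tuple[dict, ...]  # per component: name, response value, d, weight


_warned_clamp: set[str] = set()


def composite_desirability(
    point, composite: CompositeSpec, return_breakdown: bool = False
):
    """Composite desirability at one coded point or a batch of points (N, k).

    Returns a float (or length-N array).  With ``return_breakdown`` (single
    point only) returns a CompositeResult with the per-component table.
    """
    if not composite.components:
        raise ValueError("composite has no components")
    active = [c for c in composite.components if c.weight > 0]
    total_w = sum(c.weight for c in active)
    if total_w <= 0:
        raise ValueError("all composite weights are zero")
    arr = np.asarray(point, dtype=float)
    single = arr.ndim == 1
    pts = np.atleast_2d(arr)

    logsum = np.zeros(pts.shape[0])
    breakdown = []
    for comp in active:
        y = np.asarray(evaluate_surface(comp.surface, pts), dtype=float)
        if comp.clamp_nonnegative:
            if np.any(y < 0) and comp.name not in _warned_clamp:
                log.warning(
                    "component %s: negative fitted dispersion clamped to 0", comp.name
                )
                _warned_clamp.add(comp.name)
            y = np.maximum(y, 0.0)
        d = np.asarray(apply_desirability(y, comp.spec), dtype=float)
        with np.errstate(divide="ignore"):
            logsum = logsum + comp.weight * np.log(d)
        if single and return_breakdown:
            breakdown.append(
                {
                    "component": comp.name,
                    "value": float(y[0]),
                    "desirability": float(d[0]),
                    "weight": comp.weight,
                }
            )
    values = np.exp(logsum / total_w)
    if single:
        val = float(values[0])
        if return_breakdown:
            return CompositeResult(value=val, breakdown=tuple(breakdown))
        return val
    return values
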