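"""Box-constrained maximization of the composite desirability (or any objective).

The solver is deliberately deterministic: a dense grid scan over the coded
box picks the best cell (ties broken by the lexicographically smallest
point), then a bounded Nelder-Mead polish refines it.  The polished point is
kept only if it improves the objective, so the reported optimum is never
worse than the grid maximum.  Determinism makes optima reproducible and
regression-testable; the grid guards against the many local maxima a
product of piecewise-power desirabilities creates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .core import decode_point
from .desirability import (
    Component,
    CompositeSpec,
    DesirabilitySpec,
    composite_desirability,
)
from .fixtures import ExampleFixture, load_example
from .rsm import ResponseSurface, evaluate_surface

__all__ = [
    "OptimizationResult",
    "NoFeasiblePointError",
    "DEFAULT_DISPERSION_BOUND_FACTOR",
    "design_points",
    "build_composite",
    "optimize",
    "solve_example",
    "sensitivity_sweep",
]

#: Default multiplier on the worst fitted dispersion statistic over the coded
#: design points when setting the "highest acceptable" bound of its STB
#: desirability (and the symmetric NTB band of covariance components).  The
#: generous ceiling keeps dispersion statistics acting as soft preferences
#: rather than imposing feasibility constraints the mean specifications do
#: not; boundary optima are insensitive to it over roughly [3, 16].
DEFAULT_DISPERSION_BOUND_FACTOR = 6.0


#: A fitted dispersion statistic whose largest value over the design points
#: falls below this is numerically zero (percent-release units are O(1-100));
#: such a surface expresses no dispersion preference and is dropped from the
#: composite rather than turned into a desirability over rounding noise.
_NUMERICALLY_ZERO = 1e-9


class NoFeasiblePointError(RuntimeError):
    """The objective is zero (or -inf) everywhere on the search grid."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class OptimizationResult:
    coded_optimum: tuple[float, ...]
    objective_value: float
    natural_optimum: tuple[float, ...] | None = None
    breakdown: tuple[dict, ...] = ()
    grid_points_per_axis: int = 0
    n_grid_evaluations: int = 0
    polish_improved: bool = False
    conventions: dict = field(default_factory=dict)


def _grid_resolution(k: int) -> int:
    if k <= 3:
        return 41
    if k <= 5:
        return 11
    return 5


def design_points(factors) -> np.ndarray:
    """Cartesian product of the factors' coded levels, shape (N, k).

    Used to anchor dispersion desirability bounds at the fitted values over
    the experimental design region.  For very large factorials only the
    extreme levels plus the center are crossed.
    """
    level_sets = [sorted(set(f.coded_levels)) for f in factors]
    total = np.prod([len(ls) for ls in level_sets])
    if total > 100_000:
        level_sets = [
            sorted({ls[0], ls[len(ls) // 2], ls[-1]}) for ls in level_sets
        ]
    return np.array(list(itertools.product(*level_sets)), dtype=float)


def build_composite(
    config,
    surfaces: Sequence[ResponseSurface],
    anchor_points: np.ndarray | None = None,
    dispersion_bound_factor: float = DEFAULT_DISPERSION_BOUND_FACTOR,
) -> CompositeSpec:
    """Assemble the composite desirability from a study config and surfaces.

    Conventions (the published studies state none for dispersion statistics):

    * mean and scalar surfaces use the desirability class and limits of
      their response specification (NTB/LTB/STB);
    * variance and CV surfaces are smaller-the-better with lower ideal 0 and
      highest acceptable value ``dispersion_bound_factor`` times the largest
      fitted value over the design points (negative fits clamped to 0);
    * covariance surfaces are nominal-the-best with target 0 and a symmetric
      band of the same multiple of the largest fitted magnitude — robustness
      requires inter-timepoint covariances near zero;
    * weights come from the response specification (default: equal).
    """
    if anchor_points is None:
        anchor_points = design_points(config.factors)
    resp = {r.label: r for r in config.responses}
    components: list[Component] = []
    for s in surfaces:
        if s.role in ("mean", "scalar"):
            r = resp[s.response]
            if r.kind == "NTB":
                spec = DesirabilitySpec("NTB", lsl=r.lsl, target=r.target, usl=r.usl)
            elif r.kind == "LTB":
                spec = DesirabilitySpec("LTB", lsl=r.lsl, target=r.target)
            else:
                spec = DesirabilitySpec("STB", target=r.target, usl=r.usl)
            components.append(
                Component(s, spec, weight=r.weight_mean, name=s.label or s.response)
            )
        elif s.role in ("variance", "cv"):
            r = resp[s.response]
            weight = r.weight_var if s.role == "variance" else r.weight_cv
            bound = float(np.max(evaluate_surface(s, anchor_points)))
            if bound <= _NUMERICALLY_ZERO:
                # surface predicts no dispersion anywhere on the design
                continue
            spec = DesirabilitySpec(
                "STB", target=0.0, usl=bound * dispersion_bound_factor
            )
            components.append(
                Component(s, spec, weight=weight, name=s.label, clamp_nonnegative=True)
            )
        elif s.role == "covariance":
            ri, rj = (resp[lab] for lab in s.pair)
            weight = 0.5 * (ri.weight_cov + rj.weight_cov)
            band = float(np.max(np.abs(evaluate_surface(s, anchor_points))))
            if band <= _NUMERICALLY_ZERO:
                continue
            band *= dispersion_bound_factor
            spec = DesirabilitySpec("NTB", lsl=-band, target=0.0, usl=band)
            components.append(Component(s, spec, weight=weight, name=s.label))
        else:
            raise ValueError(f"surface {s.label!r}: unknown role {s.role!r}")
    return CompositeSpec([c for c in components if c.weight > 0])


def _grid(box: Sequence[tuple[float, float]], pts_per_axis: int) -> np.ndarray:
    axes = [np.linspace(lo, hi, pts_per_axis) for lo, hi in box]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([m.ravel() for m in mesh])


def optimize(
    objective: Callable,
    box: Sequence[tuple[float, float]],
    grid_points_per_axis: int | None = None,
    polish: bool = True,
    maximize: bool = True,
) -> OptimizationResult:
    """Deterministic grid scan plus bounded Nelder-Mead polish.

    ``objective`` must accept an (N, k) array and return length-N values
    (all composite/index objectives in this package do); a scalar-only
    callable is also accepted and evaluated row by row.
    """
    box = [(float(lo), float(hi)) for lo, hi in box]
    k = len(box)
    pts_per_axis = grid_points_per_axis or _grid_resolution(k)
    pts = _grid(box, pts_per_axis)
    vectorized = True
    try:
        vals = np.asarray(objective(pts), dtype=float)
        if vals.shape != (pts.shape[0],):
            raise TypeError
    except (TypeError, ValueError):
        vectorized = False
        vals = np.array([float(objective(p)) for p in pts])
    sign = 1.0 if maximize else -1.0
    svals = sign * vals
    finite = np.isfinite(svals)
    if not finite.any():
        raise NoFeasiblePointError("objective is non-finite over the entire grid")
    best_val = svals[finite].max()
    if maximize and best_val <= 0:
        raise NoFeasiblePointError(
            "objective is zero over the entire grid; some desirability component "
            "annihilates everywhere in the box"
        )
    ties = np.nonzero(finite & (svals >= best_val - 0.0))[0]
    # lexicographically smallest coded point among exact ties
    order = np.lexsort(pts[ties][:, ::-1].T)
    best_idx = ties[order[0]]
    x_best = pts[best_idx].copy()
    f_best = float(vals[best_idx])

    improved = False
    if polish:
        def scalar(x):
            x = np.asarray(x, dtype=float)
            v = objective(x[None, :]) if vectorized else objective(x)
            return -sign * float(np.asarray(v).ravel()[0])

        res = minimize(
            scalar,
            x_best,
            method="Nelder-Mead",
            bounds=box,
            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000},
        )
        cand = np.clip(res.x, [lo for lo, _ in box], [hi for _, hi in box])
        v = objective(cand[None, :]) if vectorized else objective(cand)
        f_cand = float(np.asarray(v).ravel()[0])
        if sign * f_cand > sign * f_best:
            x_best, f_best, improved = cand, f_cand, True

    return OptimizationResult(
        coded_optimum=tuple(float(v) for v in x_best),
        objective_value=f_best,
        grid_points_per_axis=pts_per_axis,
        n_grid_evaluations=int(pts.shape[0]),
        polish_improved=improved,
    )


def _annihilation_report(composite: CompositeSpec, pts: np.ndarray) -> dict:
    from .desirability import apply_desirability

    report = {}
    for comp in composite.components:
        y = np.asarray(evaluate_surface(comp.surface, pts), dtype=float)
        if comp.clamp_nonnegative:
            y = np.maximum(y, 0.0)
        d = np.asarray(apply_desirability(y, comp.spec), dtype=float)
        report[comp.name] = float(np.mean(d <= 0))
    return report


def optimize_composite(
    composite: CompositeSpec,
    box: Sequence[tuple[float, float]],
    grid_points_per_axis: int | None = None,
    polish: bool = True,
) -> OptimizationResult:
    """Maximize a composite desirability; on total infeasibility the error
    names the fraction of the grid each component annihilates."""
    objective = lambda pts: composite_desirability(pts, composite)
    try:
        return optimize(objective, box, grid_points_per_axis, polish)
    except NoFeasiblePointError as exc:
        pts = _grid([(float(lo), float(hi)) for lo, hi in box],
                    grid_points_per_axis or _grid_resolution(len(box)))
        report = _annihilation_report(composite, pts)
        worst = sorted(report.items(), key=lambda kv: -kv[1])[:5]
        detail = ", ".join(f"{name}: {frac:.0%}" for name, frac in worst)
        raise NoFeasiblePointError(
            f"{exc} (grid fraction annihilated per component: {detail})",
            diagnostics=report,
        ) from None


def solve_example(
    name: str | ExampleFixture,
    dispersion_bound_factor: float = DEFAULT_DISPERSION_BOUND_FACTOR,
    grid_points_per_axis: int | None = None,
    polish: bool = True,
) -> OptimizationResult:
    """Assemble and maximize the composite desirability of a worked example."""
    fixture = name if isinstance(name, ExampleFixture) else load_example(name)
    config = fixture.config
    composite = build_composite(
        config, fixture.surfaces, dispersion_bound_factor=dispersion_bound_factor
    )
    result = optimize_composite(composite, config.box, grid_points_per_axis, polish)
    opt = list(result.coded_optimum)
    detail = composite_desirability(np.asarray(opt), composite, return_breakdown=True)
    return OptimizationResult(
        coded_optimum=result.coded_optimum,
        objective_value=result.objective_value,
        natural_optimum=tuple(decode_point(config.factors, opt)),
        breakdown=detail.breakdown,
        grid_points_per_axis=result.grid_points_per_axis,
        n_grid_evaluations=result.n_grid_evaluations,
        polish_improved=result.polish_improved,
        conventions={
            "dispersion_bound_factor": dispersion_bound_factor,
            "weights": "per response specification (default equal)",
            "exponents": "r = s = 1",
        },
    )


def sensitivity_sweep(
    name: str | ExampleFixture,
    multipliers: Sequence[float] = (0.5, 1.0, 2.0),
    base_factor: float = DEFAULT_DISPERSION_BOUND_FACTOR,
    grid_points_per_axis: int | None = None,
) -> dict[float, OptimizationResult | NoFeasiblePointError]:
    """Re-solve an example across scalings of the dispersion-bound factor.

    The dispersion bounds are a documented convention, not published data, so
    every reproduced optimum is reported together with its stability under
    halving and doubling of those bounds.
    """
    fixture = name if isinstance(name, ExampleFixture) else load_example(name)
    out: dict[float, OptimizationResult | NoFeasiblePointError] = {}
    for mult in multipliers:
        try:
            out[mult] = solve_example(
                fixture,
                dispersion_bound_factor=base_factor * mult,
                grid_points_per_axis=grid_points_per_axis,
            )
        except NoFeasiblePointError as exc:
            out[mult] = exc
    return out
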