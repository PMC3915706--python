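"""Synthetic replicated dissolution experiments from known true surfaces.

The generator emulates the standard experimental layout: for each design run
(a coded factor setting) it draws ``m`` replicate release profiles from a
multivariate normal whose mean is the vector of true mean-surface values at
that setting and whose covariance is a user-chosen inter-timepoint matrix
Sigma.  Replicates are paired across time points, exactly the structure the
per-run covariance statistics assume.  The default replicate count is m = 3,
a typical dissolution-test batch size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .rsm import ResponseSurface, evaluate_surface
from .summary_stats import DesignTable

__all__ = ["SyntheticSpec", "generate_experiment", "factorial_design"]


def factorial_design(levels_per_factor: Sequence[Sequence[float]]) -> np.ndarray:
    """Full factorial of coded levels, shape (prod(len), k)."""
    grids = np.meshgrid(*[np.asarray(ls, dtype=float) for ls in levels_per_factor],
                        indexing="ij")
    return np.column_stack([g.ravel() for g in grids])


@dataclass
class SyntheticSpec:
    """True surfaces, design, noise model and replicate count.

    ``sigma`` may be a scalar (iid noise sd), a length-w vector of per-time
    point sds, or a full (w, w) covariance matrix; it must be positive
    semi-definite.
    """

    mean_surfaces: list[ResponseSurface]
    design: np.ndarray
    sigma: float | Sequence[float] | np.ndarray = 1.0
    m: int = 3
    labels: tuple[str, ...] = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        self.design = np.atleast_2d(np.asarray(self.design, dtype=float))
        if self.m < 2:
            raise ValueError("need m >= 2 replicates")
        if not self.mean_surfaces:
            raise ValueError("need at least one true mean surface")
        if not self.labels:
            self.labels = tuple(
                s.label or f"y{i+1}" for i, s in enumerate(self.mean_surfaces)
            )
        if len(self.labels) != len(self.mean_surfaces):
            raise ValueError("one label per mean surface required")

    @property
    def covariance(self) -> np.ndarray:
        w = len(self.mean_surfaces)
        sig = np.asarray(self.sigma, dtype=float)
        if sig.ndim == 0:
            cov = np.eye(w) * float(sig) ** 2
        elif sig.ndim == 1:
            if sig.size != w:
                raise ValueError("per-timepoint sigma length must match surfaces")
            cov = np.diag(sig**2)
        else:
            if sig.shape != (w, w):
                raise ValueError("covariance matrix must be (w, w)")
            cov = sig
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance matrix must be symmetric")
        eig = np.linalg.eigvalsh(cov)
        if eig.min() < -1e-10 * max(1.0, abs(eig).max()):
            raise ValueError("covariance matrix is not positive semi-definite")
        return cov


def generate_experiment(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> DesignTable:
    """Draw a replicated design table; deterministic under a fixed seed."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    cov = spec.covariance
    blocks = []
    for setting in spec.design:
        mu = np.array([evaluate_surface(s, setting) for s in spec.mean_surfaces])
        draws = rng.multivariate_normal(mu, cov, size=spec.m, method="svd")  # (m, w)
        blocks.append(draws.T)
    return DesignTable(
        settings=[tuple(row) for row in spec.design],
        labels=spec.labels,
        observations=blocks,
    )
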