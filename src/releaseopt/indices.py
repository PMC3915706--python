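"""Dissolution-profile comparison indices and the MSE design objective.

f1 (difference factor) and f2 (similarity factor) are the standard
regulatory indices comparing a test release profile T_t to a reference R_t
over n shared time points:

    f1 = 100 * sum|R_t - T_t| / sum R_t
    f2 = 50 * log10( 100 * [1 + mean((R_t - T_t)^2)]^(-1/2) )

Identical profiles give f1 = 0 and f2 = 100; f2 >= 50 is the conventional
similarity acceptance threshold.

The MSE objective is the competing dual-response formulation: the sum of
squared deviations of the fitted means from their targets plus the sum of
fitted variances, minimized over the coded factor box.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .rsm import ResponseSurface, evaluate_surface

__all__ = ["f1_index", "f2_index", "mse_objective"]


def _pair(reference, test) -> tuple[np.ndarray, np.ndarray]:
    R = np.asarray(reference, dtype=float).ravel()
    T = np.asarray(test, dtype=float).ravel()
    if R.size != T.size:
        raise ValueError(f"profiles differ in length ({R.size} vs {T.size})")
    if R.size < 1:
        raise ValueError("profiles must contain at least one time point")
    if not (np.all(np.isfinite(R)) and np.all(np.isfinite(T))):
        raise ValueError("profiles contain non-finite values")
    return R, T


def f1_index(reference, test) -> float:
    """Difference factor f1 (percent); 0 iff the profiles are identical."""
    R, T = _pair(reference, test)
    denom = R.sum()
    if denom == 0:
        raise ZeroDivisionError("f1 undefined: reference profile sums to zero")
    return float(100.0 * np.abs(R - T).sum() / denom)


def f2_index(reference, test) -> float:
    """Similarity factor f2; 100 iff the profiles are identical."""
    R, T = _pair(reference, test)
    msd = float(np.mean((R - T) ** 2))
    return float(50.0 * np.log10(100.0 / np.sqrt(1.0 + msd)))


def mse_objective(
    point,
    mean_surfaces: Sequence[ResponseSurface],
    variance_surfaces: Sequence[ResponseSurface],
    targets: Sequence[float],
) -> float:
    """Sum of squared mean-target deviations plus sum of fitted variances."""
    targets = np.asarray(targets, dtype=float)
    if len(mean_surfaces) != targets.size:
        raise ValueError("one target per mean surface required")
    if len(variance_surfaces) not in (0, len(mean_surfaces)):
        raise ValueError("variance surfaces must be absent or match mean surfaces")
    mu = np.array([evaluate_surface(s, point) for s in mean_surfaces])
    total = float(((mu - targets) ** 2).sum())
    for s in variance_surfaces:
        total += float(evaluate_surface(s, point))
    return total
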