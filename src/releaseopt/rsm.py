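"""Second-order response surface models in coded factors.

A surface is a polynomial over a *term set*: intercept, linear terms x_i,
pure quadratics x_i^2 and pairwise interactions x_i x_j (i < j), fitted by
ordinary least squares.  Term sets are stored per surface because published
coefficient tables sometimes omit terms, and the stepwise screener returns
a subset of the full second-order set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "Term",
    "ModelTermSet",
    "ResponseSurface",
    "SingularDesignError",
    "full_second_order",
    "build_model_matrix",
    "fit_surface",
    "evaluate_surface",
    "stepwise_select",
]


class SingularDesignError(ValueError):
    pass


@dataclass(frozen=True)
class Term:
    """A monomial, stored as per-factor exponents, e.g. (1, 0, 1) = x1*x3."""

    exponents: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "exponents", tuple(int(e) for e in self.exponents))
        if any(e < 0 for e in self.exponents):
            raise ValueError("negative exponent in model term")

    @property
    def degree(self) -> int:
        return sum(self.exponents)

    def __str__(self) -> str:
        if self.degree == 0:
            return "1"
        parts = []
        for i, e in enumerate(self.exponents):
            if e == 1:
                parts.append(f"x{i+1}")
            elif e > 1:
                parts.append(f"x{i+1}^{e}")
        return "*".join(parts)

    @classmethod
    def parse(cls, text: str, k: int) -> "Term":
        """Parse strings like ``1``, ``x2``, ``x1^2``, ``x1*x3``."""
        text = text.replace(" ", "")
        exps = [0] * k
        if text in ("1", ""):
            return cls(tuple(exps))
        for piece in text.split("*"):
            m = re.fullmatch(r"x(\d+)(?:\^(\d+))?", piece)
            if not m:
                raise ValueError(f"cannot parse model term {text!r}")
            idx = int(m.group(1)) - 1
            if not 0 <= idx < k:
                raise ValueError(f"term {text!r}: factor index out of range for k={k}")
            exps[idx] += int(m.group(2) or 1)
        return cls(tuple(exps))


@dataclass(frozen=True)
class ModelTermSet:
    """An ordered collection of distinct model terms over k factors."""

    terms: tuple[Term, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        if len(set(self.terms)) != len(self.terms):
            dupes = [str(t) for t in self.terms if list(self.terms).count(t) > 1]
            raise ValueError(f"duplicate model terms: {sorted(set(dupes))}")
        ks = {len(t.exponents) for t in self.terms}
        if len(ks) > 1:
            raise ValueError("terms disagree on the number of factors")

    @property
    def k(self) -> int:
        return len(self.terms[0].exponents)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def labels(self) -> list[str]:
        return [str(t) for t in self.terms]

    @classmethod
    def from_strings(cls, labels: Sequence[str], k: int) -> "ModelTermSet":
        return cls(tuple(Term.parse(s, k) for s in labels))


def full_second_order(k: int) -> ModelTermSet:
    """Canonical full quadratic term set: 1, x_i, x_i^2, x_i x_j (i<j)."""
    terms = [Term((0,) * k)]
    for i in range(k):
        e = [0] * k
        e[i] = 1
        terms.append(Term(tuple(e)))
    for i in range(k):
        e = [0] * k
        e[i] = 2
        terms.append(Term(tuple(e)))
    for i in range(k):
        for j in range(i + 1, k):
            e = [0] * k
            e[i] = e[j] = 1
            terms.append(Term(tuple(e)))
    return ModelTermSet(tuple(terms))


def build_model_matrix(
    settings: Sequence[Sequence[float]], terms: ModelTermSet
) -> np.ndarray:
    """One row per coded setting, one column per term (intercept first if present)."""
    X = np.atleast_2d(np.asarray(settings, dtype=float))
    if X.shape[1] != terms.k:
        raise ValueError(
            f"settings have {X.shape[1]} components, term set expects {terms.k}"
        )
    cols = [np.prod(X ** np.asarray(t.exponents, dtype=float), axis=1) for t in terms]
    return np.column_stack(cols)


@dataclass(frozen=True)
class ResponseSurface:
    """A fitted (or transcribed) polynomial response surface.

    ``role`` records which statistic the surface models: ``mean``,
    ``variance``, ``cv``, ``covariance`` or ``scalar`` (e.g. t50, MDT, f2).
    For covariance surfaces ``pair`` holds the two response labels.
    """

    terms: ModelTermSet
    coefficients: tuple[float, ...]
    role: str = "mean"
    label: str = ""
    response: str | None = None
    pair: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coefficients", tuple(float(c) for c in self.coefficients)
        )
        if len(self.coefficients) != len(self.terms):
            raise ValueError(
                f"surface {self.label!r}: {len(self.coefficients)} coefficients "
                f"for {len(self.terms)} terms"
            )
        if not all(np.isfinite(self.coefficients)):
            raise ValueError(f"surface {self.label!r}: non-finite coefficient")

    @property
    def k(self) -> int:
        return self.terms.k

    def __call__(self, point) -> float | np.ndarray:
        return evaluate_surface(self, point)


def evaluate_surface(surface: ResponseSurface, point) -> float | np.ndarray:
    """Evaluate at one coded point (length k) or a batch of points (N, k)."""
    arr = np.asarray(point, dtype=float)
    single = arr.ndim == 1
    X = build_model_matrix(np.atleast_2d(arr), surface.terms)
    vals = X @ np.asarray(surface.coefficients)
    return float(vals[0]) if single else vals


def fit_surface(
    matrix: np.ndarray,
    response: Sequence[float],
    terms: ModelTermSet | None = None,
    role: str = "mean",
    label: str = "",
    response_label: str | None = None,
    pair: tuple[str, str] | None = None,
) -> ResponseSurface:
    """Ordinary least squares fit of a response vector on a model matrix.

    The matrix must have at least as many rows as columns and full column
    rank; a rank-deficient design raises SingularDesignError naming the
    collinear columns (diagnosed via the R factor of a QR decomposition).
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(response, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("model matrix must be 2-D")
    if X.shape[0] != y.size:
        raise ValueError("response length does not match number of rows")
    if X.shape[0] < X.shape[1]:
        raise SingularDesignError(
            f"{X.shape[0]} runs cannot identify {X.shape[1]} terms"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = np.nonzero(diag < tol)[0]
        names = (
            [str(terms.terms[i]) for i in bad] if terms is not None else list(map(int, bad))
        )
        raise SingularDesignError(f"rank-deficient design; collinear terms: {names}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    if terms is None:
        # anonymous terms: degree-1 placeholders keep the surface evaluable only
        # when the caller built the matrix from an explicit term set
        raise ValueError("fit_surface requires the term set used to build the matrix")
    return ResponseSurface(
        terms=terms, coefficients=tuple(beta), role=role, label=label,
        response=response_label, pair=pair,
    )


def fit_design_table(table, terms: ModelTermSet | None = None) -> list[ResponseSurface]:
    """Fit mean/variance/cv surfaces per time point and covariance surfaces
    per time-point pair from a replicated design table.

    ``terms`` defaults to the full second-order set in the table's factors.
    Returns the surfaces in a stable order: means, variances, cvs, then
    covariances (i < j).
    """
    from .summary_stats import summarize

    stats = summarize(table)
    k = len(table.settings[0])
    terms = terms or full_second_order(k)
    X = build_model_matrix(table.settings, terms)
    labels = table.labels
    w = len(labels)
    surfaces: list[ResponseSurface] = []
    for role, attr in (("mean", "mean"), ("variance", "variance"), ("cv", "cv")):
        for q, lab in enumerate(labels):
            y = [getattr(s, attr)[q] for s in stats]
            prefix = {"mean": "mu", "variance": "var", "cv": "cv"}[role]
            surfaces.append(
                fit_surface(X, y, terms, role=role, label=f"{prefix}_{lab}", response_label=lab)
            )
    for i in range(w):
        for j in range(i + 1, w):
            y = [s.covariance[i, j] for s in stats]
            surfaces.append(
                fit_surface(
                    X, y, terms, role="covariance",
                    label=f"cov_{labels[i]}_{labels[j]}", pair=(labels[i], labels[j]),
                )
            )
    return surfaces


def _groups_by_factor(terms: ModelTermSet) -> dict[int, list[int]]:
    """Map factor index -> indices of non-intercept terms involving it."""
    groups: dict[int, list[int]] = {}
    for idx, t in enumerate(terms):
        for fi, e in enumerate(t.exponents):
            if e > 0:
                groups.setdefault(fi, []).append(idx)
    return groups


def _partial_f_pvalue(X_full, y, X_reduced) -> float:
    """p-value of the partial F test comparing nested OLS fits."""
    n = y.size

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(resid @ resid), X.shape[1]

    rss_f, p_f = rss(X_full)
    rss_r, p_r = rss(X_reduced)
    df1 = p_f - p_r
    df2 = n - p_f
    if df1 <= 0 or df2 <= 0:
        return 1.0
    if rss_f <= 0:
        return 0.0 if rss_r > rss_f else 1.0
    F = ((rss_r - rss_f) / df1) / (rss_f / df2)
    return float(_sps.f.sf(F, df1, df2))


def stepwise_select(
    matrix: np.ndarray,
    response: Sequence[float],
    terms: ModelTermSet,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.05,
    group_by_factor: bool = True,
    max_steps: int = 100,
) -> ModelTermSet:
    """Bidirectional stepwise screening of model terms.

    With ``group_by_factor`` (the default) candidate moves add or drop *all*
    terms involving one factor at once, i.e. the screening operates at the
    factor level, judged by a partial F test.  The intercept is always
    retained.  Deterministic: at each step the candidate with the smallest
    p-value enters (ties broken by canonical order), then candidates with
    the largest p-value above ``alpha_remove`` leave.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(response, dtype=float).ravel()
    n_terms = len(terms)
    intercept = [i for i, t in enumerate(terms) if t.degree == 0]
    if group_by_factor:
        units = sorted(_groups_by_factor(terms).items())  # (factor, term idxs)
    else:
        units = [(i, [i]) for i in range(n_terms) if i not in intercept]

    selected: set[int] = set()  # selected unit ids

    def cols(unit_ids: set[int]) -> list[int]:
        out = list(intercept)
        for uid, idxs in units:
            if uid in unit_ids:
                out.extend(i for i in idxs if i not in out)
        return sorted(set(out))

    for _ in range(max_steps):
        changed = False
        # forward: best unit to enter
        current = cols(selected)
        best = None
        for uid, _idxs in units:
            if uid in selected:
                continue
            trial = cols(selected | {uid})
            if len(trial) > X.shape[0] or np.linalg.matrix_rank(X[:, trial]) < len(trial):
                continue
            p = _partial_f_pvalue(X[:, trial], y, X[:, current])
            if p < alpha_enter and (best is None or p < best[0]):
                best = (p, uid)
        if best is not None:
            selected.add(best[1])
            changed = True
        # backward: worst unit to remove
        while True:
            current = cols(selected)
            worst = None
            for uid in sorted(selected):
                reduced = cols(selected - {uid})
                p = _partial_f_pvalue(X[:, current], y, X[:, reduced])
                if p > alpha_remove and (worst is None or p > worst[0]):
                    worst = (p, uid)
            if worst is None:
                break
            selected.discard(worst[1])
            current = cols(selected)
            changed = True
        if not changed:
            break
    keep = cols(selected)
    return ModelTermSet(tuple(terms.terms[i] for i in keep))
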