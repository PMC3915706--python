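"""Per-run summary statistics of replicated dissolution observations.

Each design run measures percent released at ``w`` time points on ``m``
replicate units (tablets/vessels).  Replicates are paired across time points:
replicate ``w`` of time point ``i`` and of time point ``j`` are the same
physical unit, which is what makes the inter-timepoint sample covariance
meaningful.  Statistics per run and time point: mean, sample variance
(denominator m-1), coefficient of variation s/mean, and the sample covariance
between each pair of time points.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignTable",
    "RunStatistics",
    "InsufficientReplicatesError",
    "run_mean",
    "run_variance",
    "run_cv",
    "run_covariance",
    "summarize",
    "read_design_csv",
    "write_design_csv",
]


class InsufficientReplicatesError(ValueError):
    pass


class PairingError(ValueError):
    pass


def run_mean(observations_q: Sequence[float]) -> float:
    """Arithmetic mean over the replicates of one run at one time point."""
    obs = np.asarray(observations_q, dtype=float)
    if obs.size < 1:
        raise InsufficientReplicatesError("mean needs at least one replicate")
    return float(obs.mean())


def run_variance(observations_q: Sequence[float]) -> float:
    """Sample variance over replicates, denominator m-1."""
    obs = np.asarray(observations_q, dtype=float)
    if obs.size < 2:
        raise InsufficientReplicatesError("variance needs at least two replicates")
    return float(obs.var(ddof=1))


def run_cv(observations_q: Sequence[float]) -> float:
    """Coefficient of variation: sample standard deviation over mean."""
    mean = run_mean(observations_q)
    if mean == 0:
        raise ZeroDivisionError("cv undefined: replicate mean is zero")
    return float(np.sqrt(run_variance(observations_q)) / mean)


def run_covariance(
    observations_i: Sequence[float], observations_j: Sequence[float]
) -> float:
    """Sample covariance across paired replicates of two time points."""
    a = np.asarray(observations_i, dtype=float)
    b = np.asarray(observations_j, dtype=float)
    if a.shape != b.shape:
        raise PairingError(
            f"replicate vectors differ in length ({a.size} vs {b.size})"
        )
    if a.size < 2:
        raise InsufficientReplicatesError("covariance needs at least two replicates")
    return float(np.cov(a, b, ddof=1)[0, 1])


@dataclass(frozen=True)
class RunStatistics:
    """Summary statistics of one run: arrays indexed by time point.

    ``covariance`` is the full w-by-w sample covariance matrix across
    replicates (variances on the diagonal).
    """

    setting: tuple[float, ...]
    labels: tuple[str, ...]
    mean: np.ndarray
    variance: np.ndarray
    cv: np.ndarray
    covariance: np.ndarray

    def cov_between(self, label_i: str, label_j: str) -> float:
        i, j = self.labels.index(label_i), self.labels.index(label_j)
        return float(self.covariance[i, j])


@dataclass
class DesignTable:
    """Replicated dissolution experiment: runs x time points x replicates.

    ``observations[r]`` is a (w, m) array of percent released for run ``r``;
    ``settings[r]`` is the coded factor vector of that run.
    """

    settings: list[tuple[float, ...]]
    labels: tuple[str, ...]
    observations: list[np.ndarray]

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.settings = [tuple(float(v) for v in s) for s in self.settings]
        if len(self.settings) != len(self.observations):
            raise ValueError("one setting vector per observation block required")
        w = len(self.labels)
        k = len(self.settings[0]) if self.settings else 0
        cleaned = []
        for r, block in enumerate(self.observations):
            arr = np.asarray(block, dtype=float)
            if arr.ndim != 2 or arr.shape[0] != w:
                raise ValueError(
                    f"run {r}: observation block must be (time points={w}, replicates)"
                )
            if arr.shape[1] < 2:
                raise InsufficientReplicatesError(
                    f"run {r}: needs at least 2 replicates, got {arr.shape[1]}"
                )
            cleaned.append(arr)
        m = {arr.shape[1] for arr in cleaned}
        if len(m) > 1:
            raise PairingError(f"runs have differing replicate counts {sorted(m)}")
        for r, s in enumerate(self.settings):
            if len(s) != k:
                raise ValueError(f"run {r}: setting vector length differs")
        self.observations = cleaned

    @property
    def n_runs(self) -> int:
        return len(self.settings)

    @property
    def m(self) -> int:
        return self.observations[0].shape[1]


def summarize(table: DesignTable) -> list[RunStatistics]:
    """Compute per-run mean/variance/cv and the replicate covariance matrix."""
    out = []
    for r, (setting, block) in enumerate(zip(table.settings, table.observations)):
        mean = block.mean(axis=1)
        if np.any(mean == 0):
            bad = table.labels[int(np.argmax(mean == 0))]
            raise ZeroDivisionError(f"run {r}, time point {bad}: cv undefined (mean 0)")
        cov = np.cov(block, ddof=1)  # (w, w); paired replicates across time points
        cov = np.atleast_2d(cov)
        var = np.diag(cov).copy()
        out.append(
            RunStatistics(
                setting=setting,
                labels=table.labels,
                mean=mean,
                variance=var,
                cv=np.sqrt(var) / mean,
                covariance=cov,
            )
        )
    return out


# -- CSV dialect --------------------------------------------------------------
# Long format: one row per (run, time point, replicate) with the coded factor
# values repeated on each row.  Columns: run, <factor columns>, timepoint,
# replicate, value.

_FIXED_COLS = ("run", "timepoint", "replicate", "value")


def write_design_csv(
    table: DesignTable, path: str | Path, factor_names: Sequence[str] | None = None
) -> None:
    k = len(table.settings[0])
    names = list(factor_names) if factor_names else [f"x{i+1}" for i in range(k)]
    rows = []
    for r, (setting, block) in enumerate(zip(table.settings, table.observations)):
        for qi, label in enumerate(table.labels):
            for w in range(block.shape[1]):
                row = {"run": r + 1, "timepoint": label, "replicate": w + 1,
                       "value": block[qi, w]}
                row.update(dict(zip(names, setting)))
                rows.append(row)
    pd.DataFrame(rows, columns=["run", *names, "timepoint", "replicate", "value"]).to_csv(
        path, index=False
    )


def read_design_csv(path: str | Path) -> tuple[DesignTable, list[str]]:
    """Read the long-format design CSV; returns (table, factor column names).

    The reader validates completeness: every run must carry the same time
    points and the same replicate indices.
    """
    df = pd.read_csv(path)
    missing = [c for c in _FIXED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"design CSV missing required columns: {missing}")
    factor_cols = [c for c in df.columns if c not in _FIXED_COLS]
    if not factor_cols:
        raise ValueError("design CSV has no factor columns")
    labels = list(dict.fromkeys(df["timepoint"].astype(str)))
    reps = sorted(df["replicate"].unique())
    settings, blocks = [], []
    for run_id, grp in df.groupby("run", sort=True):
        setting = grp[factor_cols].drop_duplicates()
        if len(setting) != 1:
            raise ValueError(f"run {run_id}: inconsistent factor values across rows")
        block = np.full((len(labels), len(reps)), np.nan)
        for _, row in grp.iterrows():
            qi = labels.index(str(row["timepoint"]))
            wi = reps.index(row["replicate"])
            block[qi, wi] = row["value"]
        if np.isnan(block).any():
            raise PairingError(
                f"run {run_id}: incomplete replicate/time point combinations"
            )
        settings.append(tuple(setting.iloc[0]))
        blocks.append(block)
    return DesignTable(settings=settings, labels=tuple(labels), observations=blocks), factor_cols
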