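"""Domain types for factors, coding transforms, and study configuration.

Controllable formulation/process factors (stirring speed, polymer
concentration, ...) are modelled on a linear *coded* scale,
``coded = (natural - center) / scale``, so that response surfaces and the
optimization box are dimensionless.  The coding center/scale are stored
explicitly rather than derived from the levels: published codings are not
always midpoint/half-range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "Factor",
    "TimePointSpec",
    "StudyConfig",
    "SchemaError",
    "code_value",
    "decode_value",
    "load_study_config",
    "save_study_config",
]

KINDS = ("NTB", "LTB", "STB")


class SchemaError(ValueError):
    """A study-config document is missing or mis-typing a required field."""


@dataclass(frozen=True)
class Factor:
    """A controllable variable with natural-unit levels and a linear coding.

    Parameters
    ----------
    name : str
        Factor name, e.g. ``"stirring speed"``.
    unit : str
        Natural unit, e.g. ``"rpm"``; annotation only.
    levels : tuple of float
        Natural-unit design levels (at least two distinct).
    center, scale : float
        Coding transform ``coded = (natural - center) / scale``; scale > 0.
    """

    name: str
    unit: str
    levels: tuple[float, ...]
    center: float
    scale: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(float(v) for v in self.levels))
        if not self.scale > 0:
            raise ValueError(f"factor {self.name!r}: scale must be > 0, got {self.scale}")
        if len(set(self.levels)) < 2:
            raise ValueError(f"factor {self.name!r}: needs at least 2 distinct levels")
        for v in self.levels:
            if not math.isfinite((v - self.center) / self.scale):
                raise ValueError(f"factor {self.name!r}: non-finite coded level for {v}")

    @property
    def coded_levels(self) -> tuple[float, ...]:
        return tuple(code_value(self, v) for v in self.levels)


def code_value(factor: Factor, natural: float) -> float:
    """Map a natural-unit value onto the factor's coded scale."""
    natural = float(natural)
    if not math.isfinite(natural):
        raise ValueError(f"cannot code non-finite value {natural!r}")
    return (natural - factor.center) / factor.scale


def decode_value(factor: Factor, coded: float) -> float:
    """Inverse coding: coded value back to natural units."""
    return float(coded) * factor.scale + factor.center


@dataclass(frozen=True)
class TimePointSpec:
    """Specification of one response: a profile time point or a scalar index.

    ``kind`` selects the desirability class: NTB (nominal-the-best, needs
    lsl < target < usl), LTB (larger-the-better: lsl = lowest acceptable,
    target = upper ideal) or STB (smaller-the-better: target = lower ideal,
    usl = highest acceptable).  ``time`` is in hours and is None for scalar
    responses such as t50, MDT or f2.  The four weights enter the composite
    desirability for the mean, variance, CV and covariance statistics of
    this response.
    """

    label: str
    kind: str
    time: float | None = None
    lsl: float | None = None
    target: float | None = None
    usl: float | None = None
    weight_mean: float = 1.0
    weight_var: float = 1.0
    weight_cv: float = 1.0
    weight_cov: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"response {self.label!r}: kind must be one of {KINDS}")
        if self.kind == "NTB":
            if None in (self.lsl, self.target, self.usl) or not (
                self.lsl < self.target < self.usl
            ):
                raise ValueError(
                    f"response {self.label!r}: NTB requires lsl < target < usl"
                )
        elif self.kind == "LTB":
            if None in (self.lsl, self.target) or not self.lsl < self.target:
                raise ValueError(
                    f"response {self.label!r}: LTB requires lsl (lowest acceptable) "
                    "< target (upper ideal)"
                )
        else:  # STB
            if None in (self.target, self.usl) or not self.target < self.usl:
                raise ValueError(
                    f"response {self.label!r}: STB requires target (lower ideal) "
                    "< usl (highest acceptable)"
                )
        weights = (self.weight_mean, self.weight_var, self.weight_cv, self.weight_cov)
        if any(w < 0 for w in weights):
            raise ValueError(f"response {self.label!r}: weights must be nonnegative")
        if not any(w > 0 for w in weights):
            raise ValueError(f"response {self.label!r}: at least one weight must be > 0")


@dataclass
class StudyConfig:
    """Factors, response specifications and the coded optimization box.

    ``box`` is a per-factor coded interval; the default is each factor's
    coded level range, which always contains the design points.
    """

    factors: list[Factor]
    responses: list[TimePointSpec]
    box: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.factors:
            raise SchemaError("study config needs at least one factor")
        if not self.responses:
            raise SchemaError("study config needs at least one response")
        if not self.box:
            self.box = [
                (min(f.coded_levels), max(f.coded_levels)) for f in self.factors
            ]
        if len(self.box) != len(self.factors):
            raise SchemaError("box must give one (lo, hi) interval per factor")
        self.box = [(float(lo), float(hi)) for lo, hi in self.box]
        for f, (lo, hi) in zip(self.factors, self.box):
            if not lo < hi:
                raise SchemaError(f"factor {f.name!r}: empty box interval ({lo}, {hi})")
            if min(f.coded_levels) < lo - 1e-9 or max(f.coded_levels) > hi + 1e-9:
                raise SchemaError(
                    f"factor {f.name!r}: coded design levels fall outside box ({lo}, {hi})"
                )

    @property
    def k(self) -> int:
        return len(self.factors)


# -- serialisation -----------------------------------------------------------

_FACTOR_KEYS = ("name", "unit", "levels", "center", "scale")


def _factor_from_dict(d: dict, idx: int) -> Factor:
    for key in _FACTOR_KEYS:
        if key not in d:
            raise SchemaError(f"factors[{idx}]: missing required field {key!r}")
    return Factor(
        name=str(d["name"]),
        unit=str(d["unit"]),
        levels=tuple(d["levels"]),
        center=float(d["center"]),
        scale=float(d["scale"]),
    )


def _response_from_dict(d: dict, idx: int) -> TimePointSpec:
    for key in ("label", "kind"):
        if key not in d:
            raise SchemaError(f"responses[{idx}]: missing required field {key!r}")
    weights = d.get("weights", {})
    kwargs = dict(
        label=str(d["label"]),
        kind=str(d["kind"]),
        time=None if d.get("time") is None else float(d["time"]),
    )
    for key in ("lsl", "target", "usl"):
        kwargs[key] = None if d.get(key) is None else float(d[key])
    for short, attr in (("mean", "weight_mean"), ("var", "weight_var"),
                        ("cv", "weight_cv"), ("cov", "weight_cov")):
        if short in weights:
            kwargs[attr] = float(weights[short])
    try:
        return TimePointSpec(**kwargs)
    except ValueError as exc:
        raise SchemaError(f"responses[{idx}]: {exc}") from exc


def study_config_to_dict(config: StudyConfig) -> dict:
    return {
        "factors": [
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(f).items()}
            for f in config.factors
        ],
        "responses": [
            {
                "label": r.label,
                "kind": r.kind,
                "time": r.time,
                "lsl": r.lsl,
                "target": r.target,
                "usl": r.usl,
                "weights": {
                    "mean": r.weight_mean,
                    "var": r.weight_var,
                    "cv": r.weight_cv,
                    "cov": r.weight_cov,
                },
            }
            for r in config.responses
        ],
        "box": [list(iv) for iv in config.box],
    }


def study_config_from_dict(doc: dict) -> StudyConfig:
    if not isinstance(doc, dict):
        raise SchemaError("study config document must be a mapping")
    for key in ("factors", "responses"):
        if key not in doc or not isinstance(doc[key], list) or not doc[key]:
            raise SchemaError(f"study config: missing or empty {key!r} list")
    factors = [_factor_from_dict(d, i) for i, d in enumerate(doc["factors"])]
    responses = [_response_from_dict(d, i) for i, d in enumerate(doc["responses"])]
    box = [tuple(iv) for iv in doc.get("box", [])]
    return StudyConfig(factors=factors, responses=responses, box=box)


def save_study_config(config: StudyConfig, path: str | Path) -> None:
    """Write a study config as YAML (JSON is a YAML subset and also loads)."""
    Path(path).write_text(
        yaml.safe_dump(study_config_to_dict(config), sort_keys=False)
    )


def load_study_config(path: str | Path) -> StudyConfig:
    doc = yaml.safe_load(Path(path).read_text())
    return study_config_from_dict(doc)


def code_point(factors: Sequence[Factor], natural: Sequence[float]) -> list[float]:
    """Code a whole natural-unit point, one value per factor."""
    if len(natural) != len(factors):
        raise ValueError("point length does not match number of factors")
    return [code_value(f, v) for f, v in zip(factors, natural)]


def decode_point(factors: Sequence[Factor], coded: Sequence[float]) -> list[float]:
    """Decode a whole coded point back to natural units."""
    if len(coded) != len(factors):
        raise ValueError("point length does not match number of factors")
    return [decode_value(f, v) for f, v in zip(factors, coded)]
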