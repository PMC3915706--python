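"""Packaged worked-example fixtures and the coefficient-file dialect.

Six published dissolution-optimization case studies ship with the package as
YAML data files: the study configuration (factors, codings, profile
specifications), the transcribed response-surface coefficients, and the
optimum reported in the original study for regression comparison.  The
transcriptions are verbatim, including arithmetic inconsistencies in the
source tables, which are recorded in each fixture's ``notes`` and
``coding_consistent`` flags rather than silently corrected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .core import Factor, StudyConfig, TimePointSpec, study_config_from_dict
from .rsm import ModelTermSet, ResponseSurface

__all__ = [
    "ExampleFixture",
    "EXAMPLE_NAMES",
    "load_example",
    "load_surfaces",
    "save_surfaces",
]

EXAMPLE_NAMES = (
    "diclofenac",
    "terazosin",
    "verapamil",
    "metformin",
    "ranitidine",
    "metoprolol",
)


@dataclass(frozen=True)
class ExampleFixture:
    name: str
    title: str
    config: StudyConfig
    surfaces: tuple[ResponseSurface, ...]
    reported_optimum_coded: tuple[float, ...]
    reported_optimum_natural: tuple[float, ...]
    coding_consistent: tuple[bool, ...]
    notes: tuple[str, ...]

    def surface(self, label: str) -> ResponseSurface:
        for s in self.surfaces:
            if s.label == label:
                return s
        raise KeyError(f"fixture {self.name!r} has no surface {label!r}")


def _positionalize(term: str, symbol_map: dict[str, str]) -> str:
    """Rewrite factor symbols (e.g. x7) to positional names (e.g. x3)."""
    return re.sub(r"x\d+", lambda m: symbol_map[m.group(0)], term.replace(" ", ""))


def _surfaces_from_doc(
    doc_surfaces: list[dict], symbol_map: dict[str, str] | None, k: int
) -> tuple[ResponseSurface, ...]:
    out = []
    for d in doc_surfaces:
        terms = [str(t) for t in d["terms"]]
        if symbol_map:
            terms = [_positionalize(t, symbol_map) for t in terms]
        out.append(
            ResponseSurface(
                terms=ModelTermSet.from_strings(terms, k),
                coefficients=tuple(float(c) for c in d["coefficients"]),
                role=str(d.get("role", "mean")),
                label=str(d.get("label", "")),
                response=None if d.get("response") is None else str(d["response"]),
                pair=None if d.get("pair") is None else tuple(d["pair"]),
            )
        )
    return tuple(out)


def load_example(name: str) -> ExampleFixture:
    """Load one of the packaged worked examples by name."""
    if name not in EXAMPLE_NAMES:
        raise KeyError(
            f"unknown example {name!r}; valid names: {', '.join(EXAMPLE_NAMES)}"
        )
    text = resources.files("releaseopt.data").joinpath(f"{name}.yaml").read_text()
    doc = yaml.safe_load(text)
    config = study_config_from_dict(doc)
    symbols = [str(f["symbol"]) for f in doc["factors"]]
    symbol_map = {sym: f"x{i+1}" for i, sym in enumerate(symbols)}
    surfaces = _surfaces_from_doc(doc["surfaces"], symbol_map, config.k)
    labels = {r.label for r in config.responses}
    for s in surfaces:
        if s.role == "covariance":
            if s.pair is None or not set(s.pair) <= labels:
                raise ValueError(f"{name}: covariance surface {s.label!r} has bad pair")
        elif s.response not in labels:
            raise ValueError(f"{name}: surface {s.label!r} references unknown response")
    opt = doc["reported_optimum"]
    return ExampleFixture(
        name=doc["name"],
        title=doc.get("title", ""),
        config=config,
        surfaces=surfaces,
        reported_optimum_coded=tuple(float(v) for v in opt["coded"]),
        reported_optimum_natural=tuple(float(v) for v in opt["natural"]),
        coding_consistent=tuple(bool(v) for v in opt["coding_consistent"]),
        notes=tuple(str(n) for n in doc.get("notes", [])),
    )


# -- generic coefficient files -------------------------------------------------


def save_surfaces(surfaces, path: str | Path) -> None:
    """Write surfaces to the coefficient-file dialect (YAML)."""
    doc = {
        "surfaces": [
            {
                "label": s.label,
                "role": s.role,
                "response": s.response,
                "pair": None if s.pair is None else list(s.pair),
                "terms": s.terms.labels(),
                "coefficients": [float(c) for c in s.coefficients],
            }
            for s in surfaces
        ]
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_surfaces(path: str | Path, k: int | None = None) -> tuple[ResponseSurface, ...]:
    """Read a coefficient file; ``k`` defaults to the largest factor index used."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "surfaces" not in doc:
        raise ValueError("coefficient file must contain a 'surfaces' list")
    if k is None:
        k = 0
        for d in doc["surfaces"]:
            for t in d["terms"]:
                for m in re.finditer(r"x(\d+)", str(t)):
                    k = max(k, int(m.group(1)))
        if k == 0:
            raise ValueError("cannot infer the number of factors from intercept-only terms")
    return _surfaces_from_doc(doc["surfaces"], None, k)
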