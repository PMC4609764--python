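"""End-to-end analysis pipeline and the serialized report.

``run_full_analysis`` strings the pieces together: collapse multi-arm
studies, compute per-study effects, pool with the random-effects model,
and run the three-channel p-curve.  The result is an
:class:`AnalysisReport` that round-trips losslessly through JSON (apart
from the wall-clock timestamp, which is excluded from equality and from
determinism comparisons).

``export_pcurve_bins`` reproduces the p-curve disclosure display: the
proportion of significant p-values in the five right-closed bins
(0,.01], (.01,.02], ..., (.04,.05], next to the flat 20%-per-bin null
line and the expected curve under 33% power.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .exceptions import EmptyPCurveError
from .meta import (
    EffectEstimate,
    MetaResult,
    StudyRecord,
    collapse_multiarm,
    compute_effect,
    pool_random_effects,
)
from .pcurve import (
    PCurveConfig,
    PCurveResult,
    PCurveTest,
    PPValueSet,
    ncp_for_power,
    run_pcurve,
)

__all__ = [
    "AnalysisReport",
    "run_full_analysis",
    "export_pcurve_bins",
    "corpus_digest",
    "validate_report_dict",
]

_BIN_EDGES = (0.0, 0.01, 0.02, 0.03, 0.04, 0.05)


@dataclass(frozen=True)
class AnalysisReport:
    """Everything one analysis produced, plus provenance.

    ``pcurve`` is None (with ``pcurve_error`` set) when no study survives
    the significance filter; the meta-analytic section is still emitted.
    """

    meta: MetaResult
    pcurve: PCurveResult | None
    effects: tuple[EffectEstimate, ...]
    pcurve_error: str | None = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "meta": asdict(self.meta),
            "effects": [asdict(e) for e in self.effects],
            "pcurve": None,
            "pcurve_error": self.pcurve_error,
            "provenance": dict(self.provenance),
        }
        if self.pcurve is not None:
            d["pcurve"] = {
                "tests": [asdict(t) for t in self.pcurve.tests],
                "n_significant": self.pcurve.n_significant,
                "n_excluded": self.pcurve.n_excluded,
                "inference": self.pcurve.inference,
                "pp_values": [
                    {**asdict(s), "winsorized": dict(s.winsorized)}
                    for s in self.pcurve.pp_values
                ],
            }
        return d

    def to_json(self, path: str | Path | None = None, *, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AnalysisReport":
        meta = MetaResult(**d["meta"])
        effects = tuple(EffectEstimate(**e) for e in d["effects"])
        pcurve = None
        if d.get("pcurve") is not None:
            pc = d["pcurve"]
            pcurve = PCurveResult(
                tests=tuple(PCurveTest(**t) for t in pc["tests"]),
                n_significant=pc["n_significant"],
                n_excluded=pc["n_excluded"],
                inference=pc["inference"],
                pp_values=tuple(PPValueSet(**s) for s in pc["pp_values"]),
            )
        return cls(
            meta=meta,
            pcurve=pcurve,
            effects=effects,
            pcurve_error=d.get("pcurve_error"),
            provenance=d.get("provenance", {}),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisReport":
        return cls.from_dict(json.loads(Path(path).read_text()))


def corpus_digest(studies: Sequence[StudyRecord]) -> str:
    """SHA-256 over a canonical serialization of the corpus."""
    h = hashlib.sha256()
    for s in studies:
        h.update(s.study_id.encode())
        for arm in (*s.exercise_arms, s.control_arm):
            h.update(f"|{arm.n}|{arm.mean_change!r}|{arm.sd_change!r}".encode())
        h.update(b";")
    return h.hexdigest()


def run_full_analysis(
    studies: Sequence[StudyRecord],
    config: PCurveConfig = PCurveConfig(),
    *,
    timestamp: bool = True,
) -> AnalysisReport:
    """Collapse, estimate, pool and p-curve a corpus of studies.

    Deterministic given its inputs — there is no randomness in the
    analysis path.  Requires at least two studies so the heterogeneity
    statistics are meaningful.
    """
    if len(studies) < 2:
        raise ValueError("run_full_analysis requires at least 2 studies")
    ids = [s.study_id for s in studies]
    if len(set(ids)) != len(ids):
        raise ValueError("study_id values must be unique within a corpus")

    collapsed = [collapse_multiarm(s) for s in studies]
    effects = tuple(compute_effect(s) for s in collapsed)
    meta = pool_random_effects(effects)

    pcurve = None
    pcurve_error = None
    try:
        sizes = {
            s.study_id: (s.exercise_arms[0].n, s.control_arm.n) for s in collapsed
        }
        pcurve = run_pcurve(effects, sizes, config)
    except EmptyPCurveError as exc:
        pcurve_error = str(exc)

    provenance: dict[str, Any] = {
        "package_version": __version__,
        "config": asdict(config),
        "input_digest": corpus_digest(studies),
        "n_studies_input": len(studies),
    }
    if timestamp:
        provenance["created"] = datetime.now(timezone.utc).isoformat()

    return AnalysisReport(
        meta=meta,
        pcurve=pcurve,
        effects=effects,
        pcurve_error=pcurve_error,
        provenance=provenance,
    )


def export_pcurve_bins(
    p_values: Sequence[float],
    config: PCurveConfig = PCurveConfig(),
    result: PCurveResult | None = None,
) -> pd.DataFrame:
    """Disclosure-display data for a set of significant p-values.

    Bins are right-closed — p = 0.01 falls in the first bin (0, .01].
    Observed proportions sum to 1.  The ``null_prop`` column is the flat
    0.20 expected under no effect; ``power33_prop`` is the expected bin
    mass under the 33%-power alternative, conditional on significance.

    ``result`` is accepted for symmetry with the report pipeline but the
    display depends only on the included p-values.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("export_pcurve_bins requires at least one p-value")
    if np.any((p <= 0) | (p >= config.alpha)):
        raise ValueError("all p-values must lie in (0, alpha)")

    edges = np.asarray(_BIN_EDGES)
    # right-closed: count p in (edges[j], edges[j+1]]
    counts = np.array(
        [np.sum((p > lo) & (p <= hi)) for lo, hi in zip(edges[:-1], edges[1:])]
    )
    observed = counts / p.size

    delta = ncp_for_power(config=config)
    # P(p <= x | significant) under the 33%-power alternative
    z_edges = stats.norm.isf(edges[1:] / 2.0)
    mass = stats.norm.sf(z_edges - delta) + stats.norm.cdf(-z_edges - delta)
    mass = mass / mass[-1]  # condition on significance at alpha
    power33 = np.diff(np.concatenate([[0.0], mass]))

    return pd.DataFrame(
        {
            "bin": [f"({lo:g},{hi:g}]" for lo, hi in zip(edges[:-1], edges[1:])],
            "lower": edges[:-1],
            "upper": edges[1:],
            "observed_prop": observed,
            "null_prop": np.full(5, 0.2),
            "power33_prop": power33,
        }
    )


def validate_report_dict(d: dict[str, Any]) -> None:
    """Check a report dict against the shipped JSON schema.

    Supports the subset of JSON Schema the shipped schema uses (type,
    properties, required, items, enum).  Raises ``ValueError`` on the first
    violation, naming the JSON path.
    """
    schema = json.loads(
        resources.files("pcurve_meta").joinpath("schema/report.schema.json").read_text()
    )
    _check(d, schema, "$")


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
    "null": type(None),
}


def _check(value: Any, schema: dict[str, Any], path: str) -> None:
    typ = schema.get("type")
    if typ is not None:
        allowed = typ if isinstance(typ, list) else [typ]
        if not any(
            isinstance(value, _TYPES[t]) and not (t in ("integer", "number") and isinstance(value, bool))
            for t in allowed
        ):
            raise ValueError(f"{path}: expected {typ}, got {type(value).__name__}")
    if "enum" in schema and value not in schema["enum"]:
        raise ValueError(f"{path}: {value!r} not in {schema['enum']}")
    if isinstance(value, dict):
        for key in schema.get("required", []):
            if key not in value:
                raise ValueError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in value:
                _check(value[key], sub, f"{path}.{key}")
    if isinstance(value, list) and "items" in schema:
        for i, item in enumerate(value):
            _check(item, schema["items"], f"{path}[{i}]")
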