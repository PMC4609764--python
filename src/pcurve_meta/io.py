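"""Reading and writing the package's file formats.

The arm-level corpus dialect is a CSV with header
``study_id,arm,role,n,mean_change,sd_change`` and one row per arm; ``role``
is ``exercise`` or ``control``.  All other exports (per-study effects,
forest-plot data, p-curve bins) are flat CSVs built with pandas; the full
analysis report is JSON (see :mod:`pcurve_meta.report`).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .exceptions import StudyParseError
from .meta import ArmSummary, EffectEstimate, MetaResult, StudyRecord

CORPUS_COLUMNS = ["study_id", "arm", "role", "n", "mean_change", "sd_change"]

__all__ = [
    "CORPUS_COLUMNS",
    "write_studies_csv",
    "read_studies_csv",
    "effects_to_frame",
    "write_effects_csv",
    "forest_data",
    "write_forest_csv",
]


def write_studies_csv(studies: Sequence[StudyRecord], path: str | Path) -> None:
    """Write a corpus in the arm-level dialect, one row per arm.

    Exercise arms are labelled ``exercise_1, exercise_2, ...`` and the
    control arm ``control_1``; floats are written with ``repr`` precision so
    a read/write round trip is lossless.
    """
    rows = []
    for s in studies:
        for j, arm in enumerate(s.exercise_arms, start=1):
            rows.append((s.study_id, f"exercise_{j}", "exercise",
                         arm.n, repr(arm.mean_change), repr(arm.sd_change)))
        c = s.control_arm
        rows.append((s.study_id, "control_1", "control",
                     c.n, repr(c.mean_change), repr(c.sd_change)))
    df = pd.DataFrame(rows, columns=CORPUS_COLUMNS)
    df.to_csv(path, index=False)


def read_studies_csv(path: str | Path) -> list[StudyRecord]:
    """Parse an arm-level corpus CSV into StudyRecords, preserving row order.

    Validation failures (missing column, non-numeric cell, duplicate
    (study_id, arm) pair, n < 2, a study without exercise or without
    exactly one control arm) raise :class:`StudyParseError` naming the
    offending 1-based data row.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV structure
        raise StudyParseError(f"could not parse {path}: {exc}") from exc

    missing = [c for c in CORPUS_COLUMNS if c not in df.columns]
    if missing:
        raise StudyParseError(f"{path}: missing required column(s) {missing}")

    seen_arms: set[tuple[str, str]] = set()
    # study_id -> (exercise arms, control arms), insertion ordered
    grouped: dict[str, tuple[list[ArmSummary], list[ArmSummary]]] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        sid, arm, role = row.study_id, row.arm, row.role
        if role not in ("exercise", "control"):
            raise StudyParseError(
                f"{path} row {idx}: role must be 'exercise' or 'control', got {role!r}"
            )
        if (sid, arm) in seen_arms:
            raise StudyParseError(f"{path} row {idx}: duplicate arm {(sid, arm)!r}")
        seen_arms.add((sid, arm))
        try:
            n = int(row.n)
            mean_change = float(row.mean_change)
            sd_change = float(row.sd_change)
        except (TypeError, ValueError) as exc:
            raise StudyParseError(f"{path} row {idx}: non-numeric cell ({exc})") from exc
        try:
            summary = ArmSummary(n=n, mean_change=mean_change, sd_change=sd_change)
        except ValueError as exc:
            raise StudyParseError(f"{path} row {idx}: {exc}") from exc
        ex, ct = grouped.setdefault(sid, ([], []))
        (ex if role == "exercise" else ct).append(summary)

    studies = []
    for sid, (ex, ct) in grouped.items():
        if not ex:
            raise StudyParseError(f"{path}: study {sid!r} has no exercise arm")
        if len(ct) != 1:
            raise StudyParseError(
                f"{path}: study {sid!r} must have exactly one control arm, got {len(ct)}"
            )
        studies.append(StudyRecord(study_id=sid, exercise_arms=tuple(ex), control_arm=ct[0]))
    return studies


def effects_to_frame(effects: Sequence[EffectEstimate], meta: MetaResult | None = None) -> pd.DataFrame:
    """Per-study effects as a flat table, with an optional pooled summary row."""
    rows = [
        {"study_id": e.study_id, "d": e.d, "se": e.se, "z": e.z, "p": e.p}
        for e in effects
    ]
    if meta is not None:
        rows.append(
            {"study_id": "POOLED", "d": meta.pooled_d, "se": meta.pooled_se,
             "z": meta.pooled_d / meta.pooled_se, "p": float("nan")}
        )
    return pd.DataFrame(rows, columns=["study_id", "d", "se", "z", "p"])


def write_effects_csv(
    effects: Sequence[EffectEstimate], meta: MetaResult | None, path: str | Path
) -> None:
    effects_to_frame(effects, meta).to_csv(path, index=False)


def forest_data(effects: Sequence[EffectEstimate], meta: MetaResult) -> pd.DataFrame:
    """Forest-plot export: per-study d with 95% CI and normalized
    random-effects weight (percent), plus the pooled diamond row."""
    z = 1.959963984540054
    w = [1.0 / (e.v + meta.tau2) for e in effects]
    sw = sum(w)
    rows = [
        {
            "study": e.study_id,
            "d": e.d,
            "ci_low": e.d - z * e.se,
            "ci_high": e.d + z * e.se,
            "weight_pct": 100.0 * wi / sw,
        }
        for e, wi in zip(effects, w)
    ]
    rows.append(
        {"study": "POOLED", "d": meta.pooled_d, "ci_low": meta.ci_low,
         "ci_high": meta.ci_high, "weight_pct": 100.0}
    )
    return pd.DataFrame(rows, columns=["study", "d", "ci_low", "ci_high", "weight_pct"])


def write_forest_csv(effects: Sequence[EffectEstimate], meta: MetaResult, path: str | Path) -> None:
    forest_data(effects, meta).to_csv(path, index=False)
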