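"""Readers and writers for the problem formats.

Criteria travel as YAML (a list of mappings mirroring
:class:`~fitradeoff.decision_model.Criterion`); the consequence matrix as
UTF-8 CSV with a header row of criterion ids, the alternative id in the
first column and an optional ``label`` second column.  Decimal separator
is always ``.`` regardless of locale.  Loading aggregates *all*
validation problems into one error instead of stopping at the first.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .decision_model import Alternative, ConsequenceMatrix, Criterion
from .errors import ProblemValidationError

_CRITERION_FIELDS = (
    "id",
    "name",
    "direction",
    "scale_kind",
    "scale_min",
    "scale_max",
    "n_levels",
    "rank",
    "level_labels",
)


def read_criteria(path: str | Path) -> tuple[Criterion, ...]:
    """Load a criteria specification from YAML (or JSON, a YAML subset)."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, list) or not doc:
        raise ProblemValidationError([f"{path}: expected a non-empty list of criteria"])
    problems: list[str] = []
    criteria: list[Criterion] = []
    for entry in doc:
        if not isinstance(entry, dict) or "id" not in entry:
            problems.append(f"criteria entry {entry!r} is not a mapping with an 'id'")
            continue
        unknown = set(entry) - set(_CRITERION_FIELDS)
        if unknown:
            problems.append(f"criterion {entry['id']!r}: unknown fields {sorted(unknown)}")
            continue
        kwargs = dict(entry)
        if "level_labels" in kwargs and kwargs["level_labels"] is not None:
            kwargs["level_labels"] = tuple(kwargs["level_labels"])
        try:
            criteria.append(Criterion(**kwargs))
        except (TypeError, ValueError) as exc:
            problems.append(str(exc))
    if problems:
        raise ProblemValidationError(problems)
    return tuple(criteria)


def write_criteria(criteria: Sequence[Criterion], path: str | Path) -> None:
    doc = []
    for c in criteria:
        entry = {
            f: getattr(c, f)
            for f in _CRITERION_FIELDS
            if getattr(c, f) is not None and getattr(c, f) != ""
        }
        if "level_labels" in entry:
            entry["level_labels"] = list(entry["level_labels"])
        doc.append(entry)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


def _format_number(v: float) -> str:
    return format(float(v), ".12g")


def read_matrix(path: str | Path, criteria: Sequence[Criterion]) -> ConsequenceMatrix:
    """Load and validate a consequence matrix against its criteria."""
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ProblemValidationError([f"{path}: empty matrix file"]) from None
    problems: list[str] = []
    cols = list(frame.columns)
    if not cols or cols[0] != "alternative":
        raise ProblemValidationError(
            [f"{path}: first CSV column must be 'alternative' (got {cols[:1]})"]
        )
    has_label = len(cols) > 1 and cols[1] == "label"
    data_cols = cols[2:] if has_label else cols[1:]
    expected = [c.id for c in criteria]
    if data_cols != expected:
        unknown = [c for c in data_cols if c not in expected]
        missing = [c for c in expected if c not in data_cols]
        if unknown:
            problems.append(f"unknown criterion ids in header: {unknown}")
        if missing:
            problems.append(f"criteria missing from header: {missing}")
        if not unknown and not missing:
            problems.append(f"criterion columns out of order: {data_cols} != {expected}")
        raise ProblemValidationError([f"{path}: {p}" for p in problems])
    if len(frame) == 0:
        raise ProblemValidationError([f"{path}: matrix has no alternatives"])
    alternatives = [
        Alternative(id=row["alternative"], label=row["label"] if has_label else "")
        for _, row in frame.iterrows()
    ]
    x = np.full((len(frame), len(criteria)), np.nan)
    for i, (_, row) in enumerate(frame.iterrows()):
        for j, cid in enumerate(expected):
            cell = row[cid].strip()
            try:
                x[i, j] = float(cell)
            except ValueError:
                problems.append(
                    f"non-numeric entry {cell!r} at row {row['alternative']!r}, column {cid!r}"
                )
    if problems:
        raise ProblemValidationError([f"{path}: {p}" for p in problems])
    try:
        return ConsequenceMatrix(
            alternatives=tuple(alternatives), criteria=tuple(criteria), x=x
        )
    except ProblemValidationError as exc:
        raise ProblemValidationError([f"{path}: {p}" for p in exc.violations]) from None


def write_matrix(matrix: ConsequenceMatrix, path: str | Path) -> None:
    has_labels = any(a.label for a in matrix.alternatives)
    header = ["alternative"] + (["label"] if has_labels else []) + [c.id for c in matrix.criteria]
    lines = [",".join(header)]
    for i, alt in enumerate(matrix.alternatives):
        cells = [alt.id] + ([alt.label] if has_labels else [])
        cells += [_format_number(v) for v in matrix.x[i]]
        lines.append(",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_problem(matrix_path: str | Path, criteria_path: str | Path):
    """Load criteria + matrix into a validated ProblemFixture."""
    from .synthetic_data import ProblemFixture

    criteria = read_criteria(criteria_path)
    matrix = read_matrix(matrix_path, criteria)
    return ProblemFixture(
        criteria=criteria, matrix=matrix, provenance=str(matrix_path)
    )


def read_answers(path: str | Path) -> list[str]:
    """Scripted decision-maker answers: a JSON list of
    prefer_a/prefer_b/indifferent strings."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if not isinstance(doc, list) or not all(isinstance(a, str) for a in doc):
        raise ProblemValidationError([f"{path}: expected a JSON list of answer strings"])
    return doc


def write_session_log(recommendation, path: str | Path) -> None:
    """Session log as JSON lines, one record per answered question."""
    payload = recommendation.to_json()
    with open(path, "w", encoding="utf-8") as fh:
        for record in payload["log"]:
            fh.write(json.dumps(record) + "\n")
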