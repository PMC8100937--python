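"""Robustness analysis by perturbation of the consequence matrix.

Each cycle redraws every selected performance ``p`` uniformly from
``[(1 - f) * p, (1 + f) * p]`` (the study uses f = 0.20, i.e. +/-20%),
clamps the result back into the column's nominal extremes so the
consequence space keeps its original limits, rounds ordinal entries to
integer levels, then re-normalizes and re-screens.  The report counts, per
alternative, in how many cycles it appeared in the potentially-optimal
subset — a recommendation is robust when it keeps appearing whatever the
perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .decision_model import ConsequenceMatrix, column_anchors, normalize_matrix
from .elicitation import screen
from .weight_space import WeightSpace


@dataclass(frozen=True)
class SensitivityConfig:
    """Settings of one sensitivity run.

    ``fraction`` is the relative perturbation half-width (0.2 = +/-20%);
    ``perturb_criteria`` selects the criterion ids to perturb (None = all).
    """

    fraction: float = 0.2
    n_cycles: int = 200
    seed: int = 0
    perturb_criteria: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


@dataclass(frozen=True)
class SensitivityReport:
    """Appearance counts of each alternative across perturbation cycles."""

    appearances: dict[str, int]
    in_original: dict[str, bool]
    n_cycles: int
    seed: int
    fraction: float = 0.2

    def __post_init__(self) -> None:
        for aid, count in self.appearances.items():
            if not 0 <= count <= self.n_cycles:
                raise ValueError(f"appearance count {count} of {aid!r} outside 0..{self.n_cycles}")

    def to_json(self) -> dict:
        out: dict = {
            aid: {"appearances": self.appearances[aid], "in_original": self.in_original[aid]}
            for aid in sorted(self.appearances)
        }
        out["n_cycles"] = self.n_cycles
        out["seed"] = self.seed
        return out


def perturb_matrix(
    raw: ConsequenceMatrix,
    fraction: float,
    rng: np.random.Generator,
    perturb_criteria: Sequence[str] | None = None,
) -> ConsequenceMatrix:
    """One perturbed copy of the matrix.

    Every selected entry ``p`` is drawn uniformly from
    ``[(1 - fraction) * p, (1 + fraction) * p]``, then clamped into the
    column's nominal [min, max]; ordinal entries are additionally rounded
    half-up to the nearest integer level before clamping, keeping the
    matrix type-valid.
    """
    if fraction < 0:
        raise ValueError("fraction must be >= 0")
    selected = (
        set(perturb_criteria)
        if perturb_criteria is not None
        else {c.id for c in raw.criteria}
    )
    x = np.array(raw.x, dtype=float)
    for j, crit in enumerate(raw.criteria):
        if crit.id not in selected:
            continue
        col = x[:, j]
        col_min, col_max = float(col.min()), float(col.max())
        lo = np.minimum(col * (1.0 - fraction), col * (1.0 + fraction))
        hi = np.maximum(col * (1.0 - fraction), col * (1.0 + fraction))
        drawn = rng.uniform(lo, hi)
        if crit.scale_kind == "ordinal":
            drawn = np.floor(drawn + 0.5)  # round half-up to integer levels
        x[:, j] = np.clip(drawn, col_min, col_max)
    return ConsequenceMatrix(alternatives=raw.alternatives, criteria=raw.criteria, x=x)


def sensitivity_analysis(
    problem,
    space: WeightSpace,
    config: SensitivityConfig,
    anchor_policy: str = "auto",
) -> SensitivityReport:
    """Run the perturb -> normalize -> screen loop and count subset
    membership per alternative.  Reproducible given ``config.seed``."""
    raw: ConsequenceMatrix = getattr(problem, "matrix", problem)
    rng = np.random.default_rng(config.seed)
    # Value functions are anchored once on the nominal matrix; perturbed
    # performances are evaluated under those same functions.
    anchors = column_anchors(raw, anchor_policy)
    base = screen(normalize_matrix(raw, anchor_policy, anchors=anchors), space)
    in_original = {a.id: a.id in base.potentially_optimal for a in raw.alternatives}
    counts = {a.id: 0 for a in raw.alternatives}
    for _ in range(config.n_cycles):
        perturbed = perturb_matrix(raw, config.fraction, rng, config.perturb_criteria)
        result = screen(normalize_matrix(perturbed, anchor_policy, anchors=anchors), space)
        for aid in result.potentially_optimal:
            counts[aid] += 1
    return SensitivityReport(
        appearances=counts,
        in_original=in_original,
        n_cycles=config.n_cycles,
        seed=config.seed,
        fraction=config.fraction,
    )
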