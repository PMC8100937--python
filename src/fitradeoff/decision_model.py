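"""Additive value model: criteria, consequence matrices, and normalization.

The model is the classic additive (MAVT) aggregation

    v(a_i) = sum_j  w_j * v_j(a_i),

where each per-criterion value function v_j maps the raw performance
``x[i][j]`` linearly onto [0, 1] (increasing for ``maximize`` criteria,
decreasing for ``minimize``) and the scale constants ``w_j`` are
nonnegative and sum to one.  The anchors of each linear value function are
either the criterion's declared scale bounds or the observed column range;
see :func:`normalize_matrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .errors import DegenerateColumnError, ProblemValidationError

DIRECTIONS = ("maximize", "minimize")
SCALE_KINDS = ("continuous", "ordinal")
#: ``auto`` uses declared bounds where a criterion has them (ordinal scales
#: always do) and the observed column range otherwise.
ANCHOR_POLICIES = ("declared_bounds", "observed_range", "auto")

#: tolerance for simplex-sum and [0, 1] containment checks
ATOL = 1e-9


@dataclass(frozen=True)
class Criterion:
    """One evaluation axis of the decision problem.

    Parameters
    ----------
    id : str
        Short unique identifier (used as CSV column header).
    name : str
        Human-readable name.
    direction : {"maximize", "minimize"}
        Whether larger or smaller raw performances are preferred.
    scale_kind : {"continuous", "ordinal"}
        Ordinal criteria take integer levels; continuous ones any real.
    scale_min, scale_max : float, optional
        Declared scale bounds.  Required for ordinal criteria; optional for
        continuous ones (absent bounds force observed-range anchoring).
    n_levels : int, optional
        Number of ordinal levels; must satisfy
        ``scale_max - scale_min == n_levels - 1``.
    rank : int, optional
        Importance rank, 1 = most important.
    level_labels : tuple of str, optional
        Display labels for ordinal levels (metadata only).
    """

    id: str
    name: str
    direction: str
    scale_kind: str
    scale_min: float | None = None
    scale_max: float | None = None
    n_levels: int | None = None
    rank: int | None = None
    level_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"criterion {self.id!r}: direction must be one of {DIRECTIONS}")
        if self.scale_kind not in SCALE_KINDS:
            raise ValueError(f"criterion {self.id!r}: scale_kind must be one of {SCALE_KINDS}")
        if (self.scale_min is None) != (self.scale_max is None):
            raise ValueError(f"criterion {self.id!r}: scale bounds must be given together")
        if self.scale_min is not None and not self.scale_min < self.scale_max:
            raise ValueError(f"criterion {self.id!r}: scale_min must be < scale_max")
        if self.scale_kind == "ordinal":
            if self.n_levels is None or int(self.n_levels) != self.n_levels or self.n_levels < 2:
                raise ValueError(f"criterion {self.id!r}: ordinal scale needs integer n_levels >= 2")
            if self.scale_min is None:
                raise ValueError(f"criterion {self.id!r}: ordinal scale needs declared bounds")
            if abs((self.scale_max - self.scale_min) - (self.n_levels - 1)) > ATOL:
                raise ValueError(
                    f"criterion {self.id!r}: ordinal bounds must span n_levels - 1 units"
                )
        if self.rank is not None and (int(self.rank) != self.rank or self.rank < 1):
            raise ValueError(f"criterion {self.id!r}: rank must be a positive integer")

    @property
    def has_bounds(self) -> bool:
        return self.scale_min is not None

    @property
    def best(self) -> float | None:
        """Most preferred declared scale endpoint (None without bounds)."""
        if not self.has_bounds:
            return None
        return self.scale_max if self.direction == "maximize" else self.scale_min

    @property
    def worst(self) -> float | None:
        """Least preferred declared scale endpoint (None without bounds)."""
        if not self.has_bounds:
            return None
        return self.scale_min if self.direction == "maximize" else self.scale_max


@dataclass(frozen=True)
class Alternative:
    """A course of action (here: a victim awaiting dispatch)."""

    id: str
    label: str = ""


@dataclass(frozen=True)
class WeightVector:
    """Scale-constant vector on the unit simplex."""

    w: tuple[float, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.w, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("weights must form a nonempty 1-D vector")
        if np.any(arr < -ATOL):
            raise ValueError("weights must be nonnegative")
        if abs(float(arr.sum()) - 1.0) > ATOL:
            raise ValueError(f"weights must sum to 1 (got {arr.sum()!r})")

    @classmethod
    def from_iterable(cls, values: Iterable[float]) -> "WeightVector":
        return cls(tuple(float(v) for v in values))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.w, dtype=float)

    def __len__(self) -> int:
        return len(self.w)


def validate_problem(
    alternatives: Sequence[Alternative],
    criteria: Sequence[Criterion],
    x: np.ndarray,
) -> list[str]:
    """Collect every invariant violation of an (alternatives, criteria, x) triple."""
    problems: list[str] = []
    n, k = len(alternatives), len(criteria)
    if n == 0:
        problems.append("no alternatives")
    if k == 0:
        problems.append("no criteria")
    ids = [a.id for a in alternatives]
    for dup in sorted({i for i in ids if ids.count(i) > 1}):
        problems.append(f"duplicate alternative id {dup!r}")
    cids = [c.id for c in criteria]
    for dup in sorted({i for i in cids if cids.count(i) > 1}):
        problems.append(f"duplicate criterion id {dup!r}")
    if x.shape != (n, k):
        problems.append(f"matrix shape {x.shape} does not match {n} alternatives x {k} criteria")
        return problems
    for i in range(n):
        for j in range(k):
            val = x[i, j]
            crit = criteria[j]
            if not np.isfinite(val):
                problems.append(
                    f"missing/non-finite entry at row {alternatives[i].id!r}, column {crit.id!r}"
                )
                continue
            if crit.has_bounds and not (
                crit.scale_min - ATOL <= val <= crit.scale_max + ATOL
            ):
                problems.append(
                    f"entry {val!r} at row {alternatives[i].id!r}, column {crit.id!r} "
                    f"outside scale [{crit.scale_min}, {crit.scale_max}]"
                )
            if crit.scale_kind == "ordinal" and np.isfinite(val) and val != int(val):
                problems.append(
                    f"non-integer ordinal entry {val!r} at row {alternatives[i].id!r}, "
                    f"column {crit.id!r}"
                )
    ranks = [c.rank for c in criteria if c.rank is not None]
    if ranks and sorted(ranks) != list(range(1, k + 1)):
        problems.append(
            f"criterion ranks {sorted(ranks)} are not a permutation of 1..{k}"
        )
    return problems


@dataclass(frozen=True, eq=False)
class ConsequenceMatrix:
    """Raw performances of each alternative on each criterion.

    ``x[i, j]`` is the performance of ``alternatives[i]`` on
    ``criteria[j]``, in the criterion's own units (km, years, ordinal
    level).  Construction validates all invariants and raises
    :class:`ProblemValidationError` listing every violation.
    """

    alternatives: tuple[Alternative, ...]
    criteria: tuple[Criterion, ...]
    x: np.ndarray

    def __post_init__(self) -> None:
        arr = np.array(self.x, dtype=float)
        arr.setflags(write=False)
        object.__setattr__(self, "x", arr)
        object.__setattr__(self, "alternatives", tuple(self.alternatives))
        object.__setattr__(self, "criteria", tuple(self.criteria))
        violations = validate_problem(self.alternatives, self.criteria, self.x)
        if violations:
            raise ProblemValidationError(violations)

    @property
    def n_alternatives(self) -> int:
        return len(self.alternatives)

    @property
    def n_criteria(self) -> int:
        return len(self.criteria)

    def column(self, j: int) -> np.ndarray:
        return self.x[:, j]

    def criterion_index(self, criterion_id: str) -> int:
        for j, c in enumerate(self.criteria):
            if c.id == criterion_id:
                return j
        raise KeyError(criterion_id)

    def rank_order(self) -> list[int]:
        """Column indices sorted by criterion rank (most important first)."""
        if any(c.rank is None for c in self.criteria):
            raise ValueError("all criteria need ranks to derive a rank order")
        return sorted(range(self.n_criteria), key=lambda j: self.criteria[j].rank)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConsequenceMatrix):
            return NotImplemented
        return (
            self.alternatives == other.alternatives
            and self.criteria == other.criteria
            and np.array_equal(self.x, other.x)
        )


def column_anchors(raw: ConsequenceMatrix, anchor_policy: str = "auto") -> np.ndarray:
    """Resolve the (lo, hi) anchors of every criterion's linear value function.

    Returns a ``(k, 2)`` array.  Under ``declared_bounds`` the declared
    scale endpoints anchor the function; under ``observed_range`` the
    column min/max do; ``auto`` prefers declared bounds where present.
    """
    if anchor_policy not in ANCHOR_POLICIES:
        raise ValueError(f"anchor_policy must be one of {ANCHOR_POLICIES}")
    out = np.empty((raw.n_criteria, 2), dtype=float)
    for j, crit in enumerate(raw.criteria):
        use_declared = anchor_policy == "declared_bounds" or (
            anchor_policy == "auto" and crit.has_bounds
        )
        if use_declared:
            if not crit.has_bounds:
                raise ValueError(
                    f"criterion {crit.id!r} has no declared bounds; cannot use declared_bounds"
                )
            lo, hi = crit.scale_min, crit.scale_max
        else:
            col = raw.column(j)
            lo, hi = float(col.min()), float(col.max())
            if hi - lo <= ATOL:
                raise DegenerateColumnError(
                    f"criterion {crit.id!r} has constant observed performances "
                    f"({lo}); observed-range normalization is undefined"
                )
        out[j] = (lo, hi)
    return out


def value_function(x: float, direction: str, lo: float, hi: float) -> float:
    """Linear per-criterion value of a raw performance, on [0, 1]."""
    v = (x - lo) / (hi - lo)
    if direction == "minimize":
        v = 1.0 - v
    return float(min(1.0, max(0.0, v)))


def inverse_value(v: float, direction: str, lo: float, hi: float) -> float:
    """Raw performance whose linear value equals ``v`` (inverse of
    :func:`value_function`)."""
    if direction == "minimize":
        v = 1.0 - v
    return float(lo + v * (hi - lo))


@dataclass(frozen=True, eq=False)
class ValueMatrix:
    """Normalized per-criterion values ``v[i, j]`` in [0, 1].

    Carries the anchors actually used so downstream consumers (tradeoff
    question construction) can evaluate the same value functions.
    """

    alternatives: tuple[Alternative, ...]
    criteria: tuple[Criterion, ...]
    v: np.ndarray
    anchor_policy: str
    anchors: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.array(self.v, dtype=float)
        if np.any(arr < -ATOL) or np.any(arr > 1.0 + ATOL):
            raise ValueError("value matrix entries must lie in [0, 1]")
        arr.setflags(write=False)
        object.__setattr__(self, "v", arr)
        anch = np.array(self.anchors, dtype=float)
        anch.setflags(write=False)
        object.__setattr__(self, "anchors", anch)

    @property
    def n_alternatives(self) -> int:
        return len(self.alternatives)

    @property
    def n_criteria(self) -> int:
        return len(self.criteria)

    def row(self, i: int) -> np.ndarray:
        return self.v[i]

    def rank_order(self) -> list[int]:
        if any(c.rank is None for c in self.criteria):
            raise ValueError("all criteria need ranks to derive a rank order")
        return sorted(range(self.n_criteria), key=lambda j: self.criteria[j].rank)


def normalize_matrix(
    raw: ConsequenceMatrix, anchor_policy: str = "auto", anchors: np.ndarray | None = None
) -> ValueMatrix:
    """Intracriteria evaluation: map raw performances onto [0, 1].

    For ``maximize`` criteria ``v = (x - lo) / (hi - lo)``; for
    ``minimize`` criteria ``v = (hi - x) / (hi - lo)``, with ``(lo, hi)``
    resolved by :func:`column_anchors` under ``anchor_policy``.  A constant
    column is permitted under declared bounds (it maps to a constant value)
    but rejected under observed-range anchoring.

    Pre-resolved ``anchors`` may be passed to evaluate a matrix under
    another matrix's value functions (used by the sensitivity analysis,
    which keeps the nominal anchors fixed while perturbing performances);
    values are clipped to [0, 1] against those anchors.
    """
    if anchors is None:
        anchors = column_anchors(raw, anchor_policy)
    else:
        anchors = np.asarray(anchors, dtype=float)
        if anchors.shape != (raw.n_criteria, 2):
            raise ValueError("anchors must have shape (k, 2)")
    v = np.empty_like(raw.x)
    for j, crit in enumerate(raw.criteria):
        lo, hi = anchors[j]
        col = (raw.column(j) - lo) / (hi - lo)
        if crit.direction == "minimize":
            col = 1.0 - col
        v[:, j] = np.clip(col, 0.0, 1.0)
    return ValueMatrix(
        alternatives=raw.alternatives,
        criteria=raw.criteria,
        v=v,
        anchor_policy=anchor_policy,
        anchors=anchors,
    )


def global_value(values_row: Sequence[float], weights: WeightVector | Sequence[float]) -> float:
    """Additive global value ``sum_j w_j * v_j`` of one alternative."""
    if isinstance(weights, WeightVector):
        w = weights.as_array()
    else:
        w = WeightVector.from_iterable(weights).as_array()
    row = np.asarray(values_row, dtype=float)
    if row.shape != w.shape:
        raise ValueError(f"row length {row.size} does not match weight length {w.size}")
    return float(row @ w)


class RankedAlternative(NamedTuple):
    alternative: Alternative
    value: float
    tied: bool


def rank_alternatives(
    V: ValueMatrix, weights: WeightVector | Sequence[float], tie_tol: float = 1e-12
) -> list[RankedAlternative]:
    """Order alternatives by descending global value.

    Ties (values within ``tie_tol``) are broken by alternative id lexical
    order and flagged ``tied=True`` on every member of the tie group.
    """
    scored = [
        (global_value(V.row(i), weights), V.alternatives[i]) for i in range(V.n_alternatives)
    ]
    scored.sort(key=lambda t: (-t[0], t[1].id))
    out: list[RankedAlternative] = []
    for idx, (val, alt) in enumerate(scored):
        tied = any(
            abs(val - scored[other][0]) <= tie_tol
            for other in (idx - 1, idx + 1)
            if 0 <= other < len(scored)
        )
        out.append(RankedAlternative(alt, val, tied))
    return out
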