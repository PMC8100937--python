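"""Partial information about scale constants as a linear constraint system.

The admissible weight vectors form a polytope inside the unit simplex:
the simplex constraints themselves, the decision maker's criteria ranking
``w_1 >= w_2 >= ... >= w_k`` (criteria indexed in rank order), and any
inequalities elicited from tradeoff questions.  All queries (feasibility,
per-criterion weight ranges) are linear programs, solved with HiGHS via
``scipy.optimize.linprog``.

For a ranking-only space the range endpoints have a closed form that the
test suite uses as an independent oracle: the maximum feasible weight of
the rank-``m`` criterion is ``1/m`` (uniform over the top ``m`` criteria)
and the minimum of the top-ranked criterion is ``1/k``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy.optimize import linprog

from .errors import InfeasibleWeightSpaceError

RELATIONS = ("ge", "le", "eq")

#: margin used to realize strict inequalities inside LPs
DEFAULT_EPSILON = 1e-6


def round_half_up(x: float, decimals: int) -> float:
    """Round with ties away from zero at ``decimals`` places (half-up)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class LinearConstraint:
    """One linear constraint ``coefficients . w  <relation>  rhs``.

    ``strict`` marks a strict inequality, realized at solve time by an
    epsilon margin.  ``origin`` records provenance (simplex, ranking, or an
    elicited preference) for reporting and session replay.
    """

    coefficients: tuple[float, ...]
    relation: str
    rhs: float
    strict: bool = False
    origin: str = "preference"

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))
        if self.relation not in RELATIONS:
            raise ValueError(f"relation must be one of {RELATIONS}")
        if self.strict and self.relation == "eq":
            raise ValueError("strict only applies to ge/le relations")

    @property
    def k(self) -> int:
        return len(self.coefficients)

    def satisfied_by(self, w: Sequence[float], epsilon: float = 0.0, atol: float = 1e-9) -> bool:
        lhs = float(np.dot(self.coefficients, np.asarray(w, dtype=float)))
        margin = epsilon if self.strict else 0.0
        if self.relation == "ge":
            return lhs >= self.rhs + margin - atol
        if self.relation == "le":
            return lhs <= self.rhs - margin + atol
        return abs(lhs - self.rhs) <= atol


@dataclass(frozen=True)
class WeightSpace:
    """Feasible set of scale-constant vectors, described by constraints.

    Always contains the simplex constraints; immutable — adding a
    constraint returns a new space.
    """

    k: int
    constraints: tuple[LinearConstraint, ...]
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("weight space needs k >= 1 criteria")
        if not 0 < self.epsilon <= 1e-4:
            raise ValueError("epsilon must lie in (0, 1e-4]")
        object.__setattr__(self, "constraints", tuple(self.constraints))
        for c in self.constraints:
            if c.k != self.k:
                raise ValueError(
                    f"constraint dimension {c.k} does not match space dimension {self.k}"
                )
        if not any(c.origin == "simplex" for c in self.constraints):
            raise ValueError("weight space must carry its simplex constraints")

    def contains(self, w: Sequence[float], atol: float = 1e-9) -> bool:
        """Membership check with strict constraints enforced at margin epsilon."""
        return all(c.satisfied_by(w, epsilon=self.epsilon, atol=atol) for c in self.constraints)


def simplex_constraints(k: int) -> list[LinearConstraint]:
    eye = np.eye(k)
    cons = [LinearConstraint(tuple(np.ones(k)), "eq", 1.0, origin="simplex")]
    cons += [LinearConstraint(tuple(eye[j]), "ge", 0.0, origin="simplex") for j in range(k)]
    return cons


def ranking_space(
    k: int, rank_order: Sequence[int] | None = None, epsilon: float = DEFAULT_EPSILON
) -> WeightSpace:
    """Weight space of a ranked-criteria problem.

    ``rank_order`` gives coordinate indices from most to least important;
    by default coordinate ``j`` holds the criterion ranked ``j + 1``, so
    the ranking constraints read ``w_1 >= w_2 >= ... >= w_k``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    order = list(range(k)) if rank_order is None else list(rank_order)
    if sorted(order) != list(range(k)):
        raise ValueError("rank_order must be a permutation of 0..k-1")
    cons = simplex_constraints(k)
    for a, b in zip(order, order[1:]):
        coef = np.zeros(k)
        coef[a], coef[b] = 1.0, -1.0
        cons.append(LinearConstraint(tuple(coef), "ge", 0.0, origin="ranking"))
    return WeightSpace(k=k, constraints=tuple(cons), epsilon=epsilon)


def add_constraint(space: WeightSpace, c: LinearConstraint) -> WeightSpace:
    """Intersect the feasible set with one more constraint (returns a new space)."""
    if c.k != space.k:
        raise ValueError(f"constraint dimension {c.k} does not match space dimension {space.k}")
    return replace(space, constraints=space.constraints + (c,))


def _lp_arrays(space: WeightSpace):
    """Assemble (A_ub, b_ub, A_eq, b_eq) with strict margins applied."""
    A_ub: list[np.ndarray] = []
    b_ub: list[float] = []
    A_eq: list[np.ndarray] = []
    b_eq: list[float] = []
    for c in space.constraints:
        coef = np.asarray(c.coefficients, dtype=float)
        margin = space.epsilon if c.strict else 0.0
        if c.relation == "eq":
            A_eq.append(coef)
            b_eq.append(c.rhs)
        elif c.relation == "le":
            A_ub.append(coef)
            b_ub.append(c.rhs - margin)
        else:  # ge  ->  -coef . w <= -(rhs + margin)
            A_ub.append(-coef)
            b_ub.append(-(c.rhs + margin))
    to2d = lambda rows: np.vstack(rows) if rows else None
    return (
        to2d(A_ub),
        np.asarray(b_ub) if b_ub else None,
        to2d(A_eq),
        np.asarray(b_eq) if b_eq else None,
    )


def solve_lp(space: WeightSpace, objective: Sequence[float], sense: str = "min"):
    """Optimize a linear objective over the space.

    Returns ``(optimum, w)`` in the requested sense, or raises
    :class:`InfeasibleWeightSpaceError`.  Unboundedness cannot occur (the
    simplex constraints bound the polytope).
    """
    c = np.asarray(objective, dtype=float)
    if c.size != space.k:
        raise ValueError("objective dimension mismatch")
    sign = 1.0 if sense == "min" else -1.0
    A_ub, b_ub, A_eq, b_eq = _lp_arrays(space)
    res = linprog(
        sign * c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=[(0.0, 1.0)] * space.k,
        method="highs",
    )
    if res.status == 2:
        raise InfeasibleWeightSpaceError("weight space is empty under the current constraints")
    if not res.success:  # pragma: no cover - defensive
        raise RuntimeError(f"LP solver failure: {res.message}")
    return sign * float(res.fun), np.asarray(res.x)


def is_feasible(space: WeightSpace) -> bool:
    """Whether any weight vector satisfies all constraints (strict ones at
    margin epsilon)."""
    try:
        solve_lp(space, np.zeros(space.k))
    except InfeasibleWeightSpaceError:
        return False
    return True


def feasible_point(space: WeightSpace) -> np.ndarray:
    """Some feasible weight vector (LP phase-1 solution)."""
    _, w = solve_lp(space, np.zeros(space.k))
    return w


def weight_range(space: WeightSpace, criterion_index: int) -> tuple[float, float]:
    """Minimum and maximum feasible weight of one criterion (two LPs)."""
    if not 0 <= criterion_index < space.k:
        raise IndexError("criterion_index out of range")
    obj = np.zeros(space.k)
    obj[criterion_index] = 1.0
    lo, _ = solve_lp(space, obj, sense="min")
    hi, _ = solve_lp(space, obj, sense="max")
    clip = lambda v: float(min(1.0, max(0.0, v)))
    return clip(lo), clip(hi)


@dataclass(frozen=True)
class WeightRange:
    criterion_id: str
    rank: int
    min_weight: float
    max_weight: float


@dataclass(frozen=True)
class WeightRangeReport:
    """Per-criterion weight ranges over the current space (the finalization
    report), listed in rank order."""

    entries: tuple[WeightRange, ...]
    decimals: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        for e in self.entries:
            if not (0.0 <= e.min_weight <= e.max_weight <= 1.0):
                raise ValueError(
                    f"invalid range ({e.min_weight}, {e.max_weight}) for {e.criterion_id!r}"
                )

    def __getitem__(self, criterion_id: str) -> WeightRange:
        for e in self.entries:
            if e.criterion_id == criterion_id:
                return e
        raise KeyError(criterion_id)

    def by_rank(self, rank: int) -> WeightRange:
        for e in self.entries:
            if e.rank == rank:
                return e
        raise KeyError(rank)

    def to_json(self) -> dict:
        return {
            e.criterion_id: {"min": e.min_weight, "max": e.max_weight, "rank": e.rank}
            for e in self.entries
        }


def report_ranges(
    space: WeightSpace,
    rounding: int | None = None,
    criterion_ids: Sequence[str] | None = None,
    ranks: Sequence[int] | None = None,
) -> WeightRangeReport:
    """Weight ranges of every criterion, optionally rounded half-up.

    Without explicit ``criterion_ids``/``ranks``, coordinate ``j`` is
    assumed to hold the criterion ranked ``j + 1`` (as built by
    :func:`ranking_space` with the default order) and ids default to
    ``w1..wk``.
    """
    ids = list(criterion_ids) if criterion_ids is not None else [f"w{j+1}" for j in range(space.k)]
    rks = list(ranks) if ranks is not None else list(range(1, space.k + 1))
    if len(ids) != space.k or len(rks) != space.k:
        raise ValueError("criterion_ids/ranks length must equal space dimension")
    entries = []
    for j in range(space.k):
        lo, hi = weight_range(space, j)
        if rounding is not None:
            lo, hi = round_half_up(lo, rounding), round_half_up(hi, rounding)
            lo = min(lo, hi)  # rounding may not cross the endpoints
        entries.append(WeightRange(ids[j], rks[j], lo, hi))
    entries.sort(key=lambda e: e.rank)
    return WeightRangeReport(entries=tuple(entries), decimals=rounding)
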