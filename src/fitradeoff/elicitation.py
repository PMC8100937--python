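"""Flexible tradeoff elicitation and LP screening.

The engine alternates two moves until a single alternative remains or the
question budget runs out:

1. *Screening* — with the current weight polytope, keep every alternative
   that is potentially optimal (best for at least one feasible weight
   vector) and not LP-dominated by another survivor.
2. *Elicitation* — pose a tradeoff question comparing two hypothetical
   consequences: A has the higher-ranked criterion at an intermediate
   level and everything else at its worst outcome; B has the next-ranked
   criterion at its best outcome and everything else at worst.  Under the
   additive model the answer is a linear inequality between the two scale
   constants: preferring A means ``w_a * v_a(test_level) > w_b``.

Strict preferences only shrink the weight polytope (flexible elicitation);
exact indifference, the classic tradeoff condition, is the special case
that pins the ratio ``w_b / w_a`` down to a point.

Question selection bisects the value level on the adjacent rank pair whose
weight-ratio interval is currently widest (highest-ranked pair on ties),
so consistent answers shrink the implied ratio interval geometrically and
sessions are deterministic and replayable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .decision_model import (
    ConsequenceMatrix,
    ValueMatrix,
    inverse_value,
    normalize_matrix,
    value_function,
)
from .errors import InconsistentAnswersError, InfeasibleWeightSpaceError
from .weight_space import (
    DEFAULT_EPSILON,
    LinearConstraint,
    WeightRangeReport,
    WeightSpace,
    add_constraint,
    is_feasible,
    ranking_space,
    report_ranges,
    solve_lp,
)

ANSWERS = ("prefer_a", "prefer_b", "indifferent")

#: numeric slack for weak LP comparisons (dominance / potential optimality)
LP_TOL = 1e-9


@dataclass(frozen=True)
class TradeoffQuestion:
    """One tradeoff question between an adjacent pair of ranked criteria.

    ``consequence_a`` puts criterion ``a`` (the higher-ranked one) at
    ``test_level`` and every other criterion at its worst outcome;
    ``consequence_b`` puts criterion ``b`` at its best outcome and every
    other criterion at worst.  ``v_test`` is the normalized value of
    ``test_level`` on criterion ``a``, so under the additive model the two
    consequences are worth ``w_a * v_test`` and ``w_b``.
    """

    a_index: int
    b_index: int
    a_id: str
    b_id: str
    pair_rank: int  # rank of criterion a; b is ranked pair_rank + 1
    test_level: float
    v_test: float
    consequence_a: tuple[float, ...]
    consequence_b: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.v_test <= 1.0:
            raise ValueError("v_test must lie in [0, 1]")


@dataclass(frozen=True)
class PreferenceStatement:
    """A tradeoff question together with the decision maker's answer."""

    question: TradeoffQuestion
    answer: str

    def __post_init__(self) -> None:
        if self.answer not in ANSWERS:
            raise ValueError(f"answer must be one of {ANSWERS}")


@dataclass(frozen=True)
class ScreeningResult:
    """Outcome of one screening pass.

    ``eliminated`` pairs each dropped alternative with the survivor that
    LP-dominates it, or with ``"lp-infeasible"`` when no feasible weight
    vector makes it best.
    """

    potentially_optimal: frozenset[str]
    eliminated: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class Recommendation:
    """Final state of an elicitation session."""

    chosen: str | None
    remaining: frozenset[str]
    questions_asked: int
    constraint_log: tuple[tuple[PreferenceStatement, LinearConstraint], ...]
    weight_ranges: WeightRangeReport

    def __post_init__(self) -> None:
        if (self.chosen is not None) != (len(self.remaining) == 1):
            raise ValueError("chosen must be present exactly when remaining is a singleton")

    def to_json(self) -> dict:
        return {
            "chosen": self.chosen,
            "remaining": sorted(self.remaining),
            "questions_asked": self.questions_asked,
            "weight_ranges": self.weight_ranges.to_json(),
            "log": [
                {
                    "criterion_a": s.question.a_id,
                    "criterion_b": s.question.b_id,
                    "test_level": s.question.test_level,
                    "v_test": s.question.v_test,
                    "answer": s.answer,
                    "constraint": {
                        "coefficients": list(c.coefficients),
                        "relation": c.relation,
                        "rhs": c.rhs,
                        "strict": c.strict,
                    },
                }
                for s, c in self.constraint_log
            ],
        }


def _raw_extreme(direction: str, lo: float, hi: float, best: bool) -> float:
    if direction == "maximize":
        return hi if best else lo
    return lo if best else hi


def build_question(V: ValueMatrix, pair_rank: int, v_test: float) -> TradeoffQuestion:
    """Construct the tradeoff question at value level ``v_test`` for the
    adjacent pair ranked (``pair_rank``, ``pair_rank + 1``)."""
    order = V.rank_order()
    if not 1 <= pair_rank <= len(order) - 1:
        raise ValueError("pair_rank out of range")
    a, b = order[pair_rank - 1], order[pair_rank]
    ca, cb = V.criteria[a], V.criteria[b]
    lo_a, hi_a = V.anchors[a]
    test_level = inverse_value(v_test, ca.direction, lo_a, hi_a)
    worst = [
        _raw_extreme(c.direction, *V.anchors[j], best=False) for j, c in enumerate(V.criteria)
    ]
    cons_a = list(worst)
    cons_a[a] = test_level
    cons_b = list(worst)
    cons_b[b] = _raw_extreme(cb.direction, *V.anchors[b], best=True)
    return TradeoffQuestion(
        a_index=a,
        b_index=b,
        a_id=ca.id,
        b_id=cb.id,
        pair_rank=pair_rank,
        test_level=test_level,
        v_test=float(v_test),
        consequence_a=tuple(cons_a),
        consequence_b=tuple(cons_b),
    )


def statement_to_constraint(s: PreferenceStatement, V: ValueMatrix) -> LinearConstraint:
    """Translate an answered tradeoff question into a weight constraint.

    With ``v = v_a(test_level)``, consequence A is worth ``v * w_a`` and
    consequence B is worth ``w_b``, so:

    - ``prefer_a``     ->  ``v * w_a - w_b > 0``   (strict ge)
    - ``prefer_b``     ->  ``v * w_a - w_b < 0``   (strict le)
    - ``indifferent``  ->  ``v * w_a - w_b = 0``
    """
    q = s.question
    crit_a = V.criteria[q.a_index]
    lo, hi = V.anchors[q.a_index]
    if not (min(lo, hi) - 1e-9 <= q.test_level <= max(lo, hi) + 1e-9):
        raise ValueError(
            f"test level {q.test_level} outside the scale of criterion {q.a_id!r}"
        )
    v = value_function(q.test_level, crit_a.direction, lo, hi)
    coef = np.zeros(V.n_criteria)
    coef[q.a_index] = v
    coef[q.b_index] = -1.0
    if s.answer == "prefer_a":
        return LinearConstraint(tuple(coef), "ge", 0.0, strict=True)
    if s.answer == "prefer_b":
        return LinearConstraint(tuple(coef), "le", 0.0, strict=True)
    return LinearConstraint(tuple(coef), "eq", 0.0)


def _augmented(space: WeightSpace, rows: list[np.ndarray]) -> WeightSpace:
    for row in rows:
        space = add_constraint(
            space, LinearConstraint(tuple(row), "ge", 0.0, origin="screening")
        )
    return space


def is_potentially_optimal(
    alt_index: int,
    V: ValueMatrix,
    space: WeightSpace,
    among: Sequence[int] | None = None,
) -> bool:
    """Whether some feasible weight vector makes this alternative (weakly)
    best among ``among`` (default: all alternatives)."""
    idxs = list(range(V.n_alternatives)) if among is None else list(among)
    rows = [V.row(alt_index) - V.row(b) for b in idxs if b != alt_index]
    try:
        solve_lp(_augmented(space, rows), np.zeros(space.k))
    except InfeasibleWeightSpaceError:
        if not is_feasible(space):
            raise
        return False
    return True


def lp_dominates(
    a: int, b: int, V: ValueMatrix, space: WeightSpace, tol: float = LP_TOL
) -> bool:
    """Whether ``a`` is never worse than ``b`` over the whole weight space
    and strictly better somewhere."""
    if a == b:
        raise ValueError("an alternative cannot dominate itself")
    d = V.row(a) - V.row(b)
    lo, _ = solve_lp(space, d, sense="min")
    if lo < -tol:
        return False
    hi, _ = solve_lp(space, d, sense="max")
    return hi > tol


def screen(
    V: ValueMatrix, space: WeightSpace, among: Sequence[int] | None = None
) -> ScreeningResult:
    """One screening pass: drop alternatives that are never best or that a
    survivor LP-dominates."""
    idxs = list(range(V.n_alternatives)) if among is None else list(among)
    po = [i for i in idxs if is_potentially_optimal(i, V, space, among=idxs)]
    eliminated: list[tuple[str, str]] = [
        (V.alternatives[i].id, "lp-infeasible") for i in idxs if i not in po
    ]
    # LP dominance is transitive and antisymmetric, so "dominated by any
    # potentially optimal alternative" equals "dominated by a survivor".
    survivors: list[int] = []
    for i in po:
        dominator = next(
            (j for j in po if j != i and lp_dominates(j, i, V, space)), None
        )
        if dominator is None:
            survivors.append(i)
        else:
            eliminated.append((V.alternatives[i].id, V.alternatives[dominator].id))
    return ScreeningResult(
        potentially_optimal=frozenset(V.alternatives[i].id for i in survivors),
        eliminated=tuple(eliminated),
    )


@dataclass
class ElicitationSession:
    """Mutable state of one interactive session.

    Tracks, per adjacent rank pair, the open interval of value levels
    within which the weight ratio ``w_b / w_a`` is still unresolved;
    questions bisect the widest interval.
    """

    matrix: ConsequenceMatrix
    anchor_policy: str = "auto"
    epsilon: float = DEFAULT_EPSILON
    max_questions: int = 25
    V: ValueMatrix = field(init=False)
    space: WeightSpace = field(init=False)
    intervals: dict[int, list[float]] = field(init=False)
    questions_asked: int = 0
    log: list[tuple[PreferenceStatement, LinearConstraint]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.V = normalize_matrix(self.matrix, self.anchor_policy)
        order = self.matrix.rank_order()
        self.space = ranking_space(self.matrix.n_criteria, rank_order=order, epsilon=self.epsilon)
        self.intervals = {r: [0.0, 1.0] for r in range(1, self.matrix.n_criteria)}

    def next_question(self) -> TradeoffQuestion | None:
        """Bisection question on the least-constrained adjacent pair, or
        None when the budget is spent or every ratio is resolved.

        A pair is only askable while its interval width, scaled by the
        largest feasible weight of its higher-ranked criterion, leaves
        room beyond the strict-inequality margins: a two-sided squeeze
        needs ``(v_hi - v_lo) * w_a >= 2 * epsilon`` to stay consistent,
        so narrower intervals carry no further resolvable information.
        """
        from .weight_space import weight_range

        if self.questions_asked >= self.max_questions:
            return None
        order = self.matrix.rank_order()
        candidates = sorted(
            self.intervals.items(), key=lambda kv: (-(kv[1][1] - kv[1][0]), kv[0])
        )
        for r, (lo, hi) in candidates:
            if hi - lo <= 1e-9:
                continue
            _, w_a_max = weight_range(self.space, order[r - 1])
            if (hi - lo) * w_a_max <= 8.0 * self.epsilon:
                continue
            return build_question(self.V, r, (lo + hi) / 2.0)
        return None

    def record(self, statement: PreferenceStatement) -> LinearConstraint:
        """Apply one answered question: add its constraint, check
        consistency, and shrink the pair's ratio interval."""
        c = statement_to_constraint(statement, self.V)
        new_space = add_constraint(self.space, c)
        if not is_feasible(new_space):
            raise InconsistentAnswersError(
                f"answer {statement.answer!r} to the question comparing "
                f"{statement.question.a_id!r} (at value {statement.question.v_test:.4g}) with "
                f"{statement.question.b_id!r} contradicts earlier statements",
                statement=statement,
            )
        self.space = new_space
        r, v = statement.question.pair_rank, statement.question.v_test
        lo, hi = self.intervals[r]
        if statement.answer == "prefer_a":  # w_b / w_a < v
            self.intervals[r] = [lo, min(hi, v)]
        elif statement.answer == "prefer_b":  # w_b / w_a > v
            self.intervals[r] = [max(lo, v), hi]
        else:
            self.intervals[r] = [v, v]
        self.questions_asked += 1
        self.log.append((statement, c))
        return c


def run_session(
    problem,
    answer_provider: Callable[[TradeoffQuestion], str],
    max_questions: int = 25,
    anchor_policy: str = "auto",
    epsilon: float = DEFAULT_EPSILON,
    rounding: int | None = None,
) -> Recommendation:
    """Run a full elicitation session to a recommendation.

    ``problem`` is a :class:`ConsequenceMatrix` or anything with a
    ``matrix`` attribute holding one.  ``answer_provider`` is called with
    each :class:`TradeoffQuestion` and must return one of ``prefer_a``,
    ``prefer_b`` or ``indifferent``.  The loop screens, asks, converts the
    answer to a constraint, and repeats until one alternative remains, the
    answers turn inconsistent (raises
    :class:`~fitradeoff.errors.InconsistentAnswersError`), questions run
    out, or no informative question is left.
    """
    matrix: ConsequenceMatrix = getattr(problem, "matrix", problem)
    session = ElicitationSession(
        matrix=matrix,
        anchor_policy=anchor_policy,
        epsilon=epsilon,
        max_questions=max_questions,
    )
    survivors = list(range(matrix.n_alternatives))
    id_of = {a.id: i for i, a in enumerate(matrix.alternatives)}
    while True:
        result = screen(session.V, session.space, among=survivors)
        survivors = sorted(id_of[aid] for aid in result.potentially_optimal)
        if len(survivors) == 1:
            break
        q = session.next_question()
        if q is None:
            break
        answer = answer_provider(q)
        session.record(PreferenceStatement(question=q, answer=answer))
    remaining = frozenset(matrix.alternatives[i].id for i in survivors)
    ranges = report_ranges(
        session.space,
        rounding=rounding,
        criterion_ids=[c.id for c in matrix.criteria],
        ranks=[c.rank for c in matrix.criteria],
    )
    return Recommendation(
        chosen=next(iter(remaining)) if len(remaining) == 1 else None,
        remaining=remaining,
        questions_asked=session.questions_asked,
        constraint_log=tuple(session.log),
        weight_ranges=ranges,
    )
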