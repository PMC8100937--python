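"""Tradeoff statements, LP screening, and the elicitation loop."""

import numpy as np
import pytest

from fitradeoff import (
    Alternative,
    ConsequenceMatrix,
    Criterion,
    InconsistentAnswersError,
    PreferenceStatement,
    add_constraint,
    build_question,
    is_potentially_optimal,
    lp_dominates,
    normalize_matrix,
    ranking_space,
    run_session,
    screen,
    statement_to_constraint,
    weight_range,
)
from fitradeoff.elicitation import ElicitationSession


def make_problem(x, directions=None):
    """Continuous declared-bound [0, 1] problem with ranks = column order."""
    x = np.atleast_2d(np.asarray(x, float))
    n, k = x.shape
    directions = directions or ["maximize"] * k
    crits = tuple(
        Criterion(
            id=f"c{j+1}", name="", direction=directions[j], scale_kind="continuous",
            scale_min=0.0, scale_max=1.0, rank=j + 1,
        )
        for j in range(k)
    )
    alts = tuple(Alternative(id=f"a{i+1}") for i in range(n))
    return ConsequenceMatrix(alternatives=alts, criteria=crits, x=x)


#: two-alternative, two-criteria problem where neither alternative
#: dominates: a1 = (1, 0), a2 = (0.4, 1); a2 is best iff w2/w1 >= 0.6
TUG_OF_WAR = [[1.0, 0.0], [0.4, 1.0]]


class TestStatements:
    def test_best_level_preference_restates_the_ranking(self):
        V = normalize_matrix(make_problem(TUG_OF_WAR))
        q = build_question(V, 1, 1.0)
        c = statement_to_constraint(PreferenceStatement(q, "prefer_a"), V)
        assert c.coefficients == (1.0, -1.0)
        assert (c.relation, c.strict) == ("ge", True)

    def test_worst_level_preference_means_lower_weight_positive(self):
        V = normalize_matrix(make_problem(TUG_OF_WAR))
        q = build_question(V, 1, 0.0)
        c = statement_to_constraint(PreferenceStatement(q, "prefer_b"), V)
        # 0 * w_a <= w_b - eps, i.e. w_b must be strictly positive
        assert c.coefficients == (0.0, -1.0)
        assert (c.relation, c.strict) == ("le", True)

    def test_indifference_pins_the_weights_down(self):
        # v_a(test) = 0.6 makes the consequences equally valued exactly
        # when w_b = 0.6 w_a; with w1 + w2 = 1 that is w = (0.625, 0.375)
        V = normalize_matrix(make_problem(TUG_OF_WAR))
        q = build_question(V, 1, 0.6)
        c = statement_to_constraint(PreferenceStatement(q, "indifferent"), V)
        space = add_constraint(ranking_space(2), c)
        assert weight_range(space, 0) == pytest.approx((0.625, 0.625), abs=1e-9)
        assert weight_range(space, 1) == pytest.approx((0.375, 0.375), abs=1e-9)

    def test_out_of_scale_test_level_rejected(self):
        V = normalize_matrix(make_problem(TUG_OF_WAR))
        q = build_question(V, 1, 0.5)
        object.__setattr__(q, "test_level", 2.0)
        with pytest.raises(ValueError, match="outside the scale"):
            statement_to_constraint(PreferenceStatement(q, "prefer_a"), V)


class TestScreeningPrimitives:
    def test_weakly_dominant_row_is_potentially_optimal(self):
        V = normalize_matrix(make_problem([[0.9, 0.8], [0.5, 0.8]]))
        assert is_potentially_optimal(0, V, ranking_space(2))

    def test_strictly_dominated_row_is_not(self):
        V = normalize_matrix(make_problem([[0.9, 0.9], [0.5, 0.8]]))
        assert not is_potentially_optimal(1, V, ranking_space(2))

    def test_identical_rows_do_not_dominate_each_other(self):
        V = normalize_matrix(make_problem([[0.5, 0.5], [0.5, 0.5]]))
        space = ranking_space(2)
        assert not lp_dominates(0, 1, V, space)
        assert not lp_dominates(1, 0, V, space)

    def test_entrywise_extremes_dominate(self):
        V = normalize_matrix(make_problem([[1.0, 1.0], [0.0, 0.0]]))
        assert lp_dominates(0, 1, V, ranking_space(2))

    def test_fixture_best_victim_is_potentially_optimal(self, samu_values, samu_space):
        idx = [a.id for a in samu_values.alternatives].index("victim_2")
        assert is_potentially_optimal(idx, samu_values, samu_space)

    def test_fixture_dominance_agrees_with_randomized_search(self, samu_values, samu_space, rng):
        # counterexample hunt over 1e5 feasible weight vectors: victim 2's
        # value never drops below victim 1's anywhere in the ranked simplex
        order = samu_values.rank_order()
        by_rank = np.sort(rng.dirichlet(np.ones(10), size=100_000), axis=1)[:, ::-1]
        w = np.empty_like(by_rank)
        for pos, j in enumerate(order):
            w[:, j] = by_rank[:, pos]
        diff = w @ (samu_values.v[1] - samu_values.v[0])
        assert diff.min() >= -1e-9
        assert lp_dominates(1, 0, samu_values, samu_space)


class TestScreen:
    def test_single_alternative_survives(self):
        V = normalize_matrix(make_problem([[0.3, 0.7]]))
        result = screen(V, ranking_space(2))
        assert result.potentially_optimal == {"a1"}
        assert result.eliminated == ()

    def test_entrywise_dominant_pair_leaves_singleton(self):
        V = normalize_matrix(make_problem([[0.9, 0.9], [0.1, 0.2]]))
        result = screen(V, ranking_space(2))
        assert result.potentially_optimal == {"a1"}
        assert ("a2", "a1") in result.eliminated or ("a2", "lp-infeasible") in result.eliminated

    def test_fixture_survivors_are_potentially_optimal_and_undominated(
        self, samu_values, samu_space
    ):
        result = screen(samu_values, samu_space)
        ids = [a.id for a in samu_values.alternatives]
        po = {ids[i] for i in range(4) if is_potentially_optimal(i, samu_values, samu_space)}
        assert result.potentially_optimal <= po
        assert result.potentially_optimal == {"victim_2"}
        for loser, winner in result.eliminated:
            if winner != "lp-infeasible":
                assert lp_dominates(
                    ids.index(winner), ids.index(loser), samu_values, samu_space
                )
        assert {aid for aid, _ in result.eliminated} | result.potentially_optimal == set(ids)


class TestSessionLoop:
    def test_first_question_bisects_top_pair_at_midpoint(self):
        session = ElicitationSession(matrix=make_problem(TUG_OF_WAR))
        q = session.next_question()
        assert (q.a_id, q.b_id) == ("c1", "c2")
        assert q.v_test == 0.5

    def test_bisection_steps_into_the_preferred_half(self):
        session = ElicitationSession(matrix=make_problem(TUG_OF_WAR))
        q = session.next_question()
        session.record(PreferenceStatement(q, "prefer_a"))
        q2 = session.next_question()
        assert q2.v_test == 0.25

    def test_consistent_answers_shrink_the_interval_geometrically(self):
        session = ElicitationSession(matrix=make_problem(TUG_OF_WAR), max_questions=10)
        for round_no in range(1, 11):
            q = session.next_question()
            session.record(PreferenceStatement(q, "prefer_a"))
            lo, hi = session.intervals[1]
            assert hi - lo == pytest.approx(0.5**round_no)

    def test_contradictory_recorded_statements_raise(self):
        session = ElicitationSession(matrix=make_problem(TUG_OF_WAR))
        V = session.V
        session.record(PreferenceStatement(build_question(V, 1, 0.1), "prefer_a"))
        with pytest.raises(InconsistentAnswersError):
            session.record(PreferenceStatement(build_question(V, 1, 0.9), "prefer_b"))

    def test_dominant_alternative_needs_no_questions(self):
        rec = run_session(make_problem([[0.9, 0.9], [0.1, 0.2]]), lambda q: "prefer_a")
        assert rec.chosen == "a1"
        assert rec.questions_asked == 0

    def test_zero_budget_reports_initial_survivors(self):
        rec = run_session(make_problem(TUG_OF_WAR), lambda q: "prefer_a", max_questions=0)
        assert rec.chosen is None
        assert rec.remaining == {"a1", "a2"}

    def test_session_converges_and_log_replays(self):
        rec = run_session(make_problem(TUG_OF_WAR), lambda q: "prefer_a", max_questions=10)
        # every prefer_a answer caps w2/w1 below the bisection level; the
        # ratio interval collapses toward 0 where a1 wins
        assert rec.chosen == "a1"
        assert rec.questions_asked >= 1
        payload = rec.to_json()
        assert len(payload["log"]) == rec.questions_asked
        assert all(r["answer"] == "prefer_a" for r in payload["log"])

    def test_adding_statements_never_enlarges_the_survivor_set(self):
        matrix = make_problem(
            [[1.0, 0.0, 0.2], [0.4, 1.0, 0.0], [0.3, 0.2, 1.0], [0.2, 0.9, 0.9]]
        )
        V = normalize_matrix(matrix)
        space = ranking_space(3)
        survivors = screen(V, space).potentially_optimal
        session = ElicitationSession(matrix=matrix, max_questions=6)
        for _ in range(6):
            q = session.next_question()
            if q is None:
                break
            session.record(PreferenceStatement(q, "prefer_a"))
            now = screen(V, session.space).potentially_optimal
            assert now <= survivors
            survivors = now
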