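"""Engine behaviour: Bayes updates, question selection, sessions, evidence."""

from __future__ import annotations


import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from visiondx.bayes_engine import (
    AnswerValue,
    Termination,
    differential,
    evidence_for,
    expected_shift,
    initial_belief,
    next_question,
    predictive,
    run_session,
    should_stop,
    update,
)
from visiondx.knowledge_base import EngineParams

from conftest import joint_posterior_oracle, make_random_kb, random_answers

Y, N, U = AnswerValue.YES, AnswerValue.NO, AnswerValue.UNKNOWN


def two_dx_kb(p0: float = 0.8, p1: float = 0.2):
    rng = np.random.default_rng(0)
    kb = make_random_kb(rng, n_dx=2, n_q=3, n_seeds=3)
    lik = {q: dict(row) for q, row in kb.likelihoods.items()}
    lik["q0"] = {"d0": p0, "d1": p1}
    return kb.model_copy(update={"likelihoods": lik})


class TestUpdate:
    def test_unknown_is_identity_on_probabilities(self, kb):
        b = initial_belief(kb)
        b2 = update(b, kb, "rapd", U)
        assert b2.probs == b.probs
        assert b2.asked == {"rapd"}

    def test_two_diagnosis_yes_update_forced_by_bayes(self):
        kb = two_dx_kb(0.8, 0.2)
        # equal priors are not guaranteed by the random KB; rebuild the belief
        from visiondx.bayes_engine import BeliefState

        b = BeliefState(probs={"d0": 0.5, "d1": 0.5})
        post = update(b, kb, "q0", Y)
        assert post.probs["d0"] == pytest.approx(0.8, abs=1e-12)
        assert post.probs["d1"] == pytest.approx(0.2, abs=1e-12)
        post = update(b, kb, "q0", N)
        assert post.probs["d0"] == pytest.approx(0.2, abs=1e-12)

    def test_repeated_question_rejected(self, kb):
        b = update(initial_belief(kb), kb, "rapd", Y)
        with pytest.raises(ValueError, match="already asked"):
            update(b, kb, "rapd", N)

    def test_unknown_question_rejected(self, kb):
        with pytest.raises(KeyError):
            update(initial_belief(kb), kb, "no_such_question", Y)

    @pytest.mark.parametrize("seed", range(8))
    def test_sequential_updates_equal_joint_oracle(self, seed):
        rng = np.random.default_rng(seed)
        kb = make_random_kb(rng, n_dx=int(rng.integers(2, 7)), n_q=int(rng.integers(3, 9)))
        answers = random_answers(rng, kb)
        b = initial_belief(kb)
        for qid, ans in answers.items():
            b = update(b, kb, qid, ans)
        expected = joint_posterior_oracle(kb, answers)
        for dx in kb.diagnosis_ids:
            assert b.probs[dx] == pytest.approx(expected[dx], abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_order_invariance(self, seed):
        rng = np.random.default_rng(100 + seed)
        kb = make_random_kb(rng, n_dx=4, n_q=6)
        answers = random_answers(rng, kb)
        items = list(answers.items())
        finals = []
        for perm_seed in range(3):
            perm = np.random.default_rng(perm_seed).permutation(len(items))
            b = initial_belief(kb)
            for i in perm:
                qid, ans = items[i]
                b = update(b, kb, qid, ans)
            finals.append(b.probs)
        for probs in finals[1:]:
            for dx in kb.diagnosis_ids:
                assert probs[dx] == pytest.approx(finals[0][dx], abs=1e-12)

    @given(st.integers(0, 500))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_yes_increases_prob_iff_likelihood_beats_predictive(self, seed):
        rng = np.random.default_rng(seed)
        kb = make_random_kb(rng, n_dx=4, n_q=4)
        b = initial_belief(kb)
        qid = kb.question_ids[int(rng.integers(0, 4))]
        p_pred = predictive(b, kb, qid)
        post = update(b, kb, qid, Y)
        for dx in kb.diagnosis_ids:
            if kb.p_yes(qid, dx) > p_pred:
                assert post.probs[dx] > b.probs[dx]
            elif kb.p_yes(qid, dx) < p_pred:
                assert post.probs[dx] < b.probs[dx]


class TestPredictive:
    def test_uniform_two_diagnosis_average(self):
        kb = two_dx_kb(0.8, 0.2)
        from visiondx.bayes_engine import BeliefState

        b = BeliefState(probs={"d0": 0.5, "d1": 0.5})
        assert predictive(b, kb, "q0") == pytest.approx(0.5, abs=1e-12)

    def test_degenerate_belief_returns_conditional(self, kb):
        from visiondx.bayes_engine import BeliefState

        probs = {dx: 1e-12 for dx in kb.diagnosis_ids}
        probs["crao"] = 1.0 - 12e-12
        b = BeliefState(probs=probs)
        assert predictive(b, kb, "vision_blackout") == pytest.approx(
            kb.p_yes("vision_blackout", "crao"), abs=1e-9
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_summation(self, seed):
        rng = np.random.default_rng(200 + seed)
        kb = make_random_kb(rng, n_dx=5, n_q=5)
        b = initial_belief(kb)
        for qid in kb.question_ids:
            expected = sum(kb.priors[dx] * kb.p_yes(qid, dx) for dx in kb.diagnosis_ids)
            assert predictive(b, kb, qid) == pytest.approx(expected, abs=1e-12)
            assert 0.0 < predictive(b, kb, qid) < 1.0


class TestExpectedShift:
    def test_uninformative_question_scores_zero(self):
        rng = np.random.default_rng(3)
        kb = make_random_kb(rng, n_dx=4, n_q=3)
        lik = {q: dict(row) for q, row in kb.likelihoods.items()}
        lik["q1"] = {dx: 0.4 for dx in kb.diagnosis_ids}
        kb = kb.model_copy(update={"likelihoods": lik})
        assert expected_shift(initial_belief(kb), kb, "q1") == pytest.approx(0.0, abs=1e-12)

    def test_perfectly_discriminating_question_approaches_half(self):
        # two equiprobable diagnoses; p_yes at the clipping floor boundaries
        kb = two_dx_kb(0.99, 0.01)
        from visiondx.bayes_engine import BeliefState

        b = BeliefState(probs={"d0": 0.5, "d1": 0.5})
        assert expected_shift(b, kb, "q0") == pytest.approx(0.49, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_two_branch_enumeration(self, seed):
        rng = np.random.default_rng(300 + seed)
        kb = make_random_kb(rng, n_dx=5, n_q=5)
        b = initial_belief(kb)
        for qid in kb.question_ids:
            p = predictive(b, kb, qid)
            tv_yes = 0.5 * sum(
                abs(update(b, kb, qid, Y).probs[d] - b.probs[d]) for d in kb.diagnosis_ids
            )
            tv_no = 0.5 * sum(
                abs(update(b, kb, qid, N).probs[d] - b.probs[d]) for d in kb.diagnosis_ids
            )
            expected = p * tv_yes + (1 - p) * tv_no
            got = expected_shift(b, kb, qid)
            assert got == pytest.approx(expected, abs=1e-12)
            assert 0.0 <= got < 1.0

    def test_asked_question_rejected(self, kb):
        b = update(initial_belief(kb), kb, "rapd", Y)
        with pytest.raises(ValueError):
            expected_shift(b, kb, "rapd")


class TestNextQuestion:
    def test_fresh_session_starts_with_first_seed(self, kb):
        assert next_question(initial_belief(kb), kb) == kb.seed_questions()[0].id

    def test_all_asked_returns_none(self):
        rng = np.random.default_rng(4)
        kb = make_random_kb(rng, n_dx=3, n_q=3)
        b = initial_belief(kb)
        for qid in kb.question_ids:
            b = update(b, kb, qid, U)
        assert next_question(b, kb) is None

    @pytest.mark.parametrize("seed", range(10))
    def test_post_seed_matches_exhaustive_argmax(self, seed):
        rng = np.random.default_rng(400 + seed)
        kb = make_random_kb(rng, n_dx=int(rng.integers(2, 7)), n_q=int(rng.integers(4, 9)))
        b = initial_belief(kb)
        for q in kb.seed_questions():
            b = update(b, kb, q.id, [Y, N, U][int(rng.integers(0, 3))])
        unasked = sorted(q for q in kb.question_ids if q not in b.asked)
        scores = {q: expected_shift(b, kb, q) for q in unasked}
        best = max(scores.values())
        oracle = [q for q in unasked if scores[q] == best][0]
        assert next_question(b, kb) == oracle


class TestShouldStop:
    def make_belief(self, kb, top: float):
        rest = (1.0 - top) / (len(kb.diagnosis_ids) - 1)
        probs = {dx: rest for dx in kb.diagnosis_ids}
        probs[kb.diagnosis_ids[0]] = top
        from visiondx.bayes_engine import BeliefState

        return BeliefState(probs=probs)

    def test_dominant_top_stops(self, kb):
        assert should_stop(self.make_belief(kb, 0.90), kb)

    def test_uniform_does_not_stop(self, kb):
        probs = {dx: 1.0 / 13 for dx in kb.diagnosis_ids}
        from visiondx.bayes_engine import BeliefState

        assert not should_stop(BeliefState(probs=probs), kb)

    def test_ratio_exactly_at_threshold_stops(self):
        rng = np.random.default_rng(5)
        kb = make_random_kb(rng, n_dx=2, n_q=3)
        kb = kb.model_copy(update={"params": EngineParams(stop_ratio=5.0)})
        from visiondx.bayes_engine import BeliefState

        b = BeliefState(probs={"d0": 5.0 / 6.0, "d1": 1.0 / 6.0})
        assert should_stop(b, kb)

    def test_question_budget_forces_stop(self, kb):
        probs = {dx: 1.0 / 13 for dx in kb.diagnosis_ids}
        from visiondx.bayes_engine import BeliefState

        b = BeliefState(probs=probs, asked=frozenset(kb.question_ids[: kb.params.max_questions]))
        assert should_stop(b, kb)

    def test_stop_is_monotone_under_unknown_answers(self, kb):
        b = self.make_belief(kb, 0.95)
        assert should_stop(b, kb)
        b2 = update(b, kb, "rapd", U)
        assert should_stop(b2, kb)


class TestDifferential:
    def test_uniform_belief_yields_canonical_order(self, kb):
        from visiondx.bayes_engine import BeliefState

        b = BeliefState(probs={dx: 1.0 / 13 for dx in kb.diagnosis_ids})
        assert differential(b).top(13) == kb.diagnosis_ids

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_stable_sort_oracle(self, seed, kb):
        rng = np.random.default_rng(500 + seed)
        raw = rng.dirichlet(np.ones(13))
        from visiondx.bayes_engine import BeliefState

        probs = {dx: float(p) for dx, p in zip(kb.diagnosis_ids, raw)}
        d = differential(BeliefState(probs=probs))
        oracle = [
            dx for dx, _ in sorted(
                probs.items(),
                key=lambda it: (-it[1], kb.diagnosis_ids.index(it[0])),
            )
        ]
        assert list(d.top(13)) == oracle
        posts = [p for _, p in d.ranked]
        assert posts == sorted(posts, reverse=True)
        assert sum(posts) == pytest.approx(1.0, abs=1e-9)


class TestRunSession:
    def test_all_unknown_returns_prior_ranking(self, kb):
        t = run_session(kb, {})
        prior_order = differential(initial_belief(kb)).top(13)
        assert t.final_differential.top(13) == prior_order
        assert t.terminated_by in (Termination.MAX_QUESTIONS, Termination.EXHAUSTED)

    def test_seed_questions_open_every_session(self, kb):
        t = run_session(kb, {})
        seed_ids = [q.id for q in kb.seed_questions()]
        assert [s.question_id for s in t.steps[: len(seed_ids)]] == seed_ids

    def test_question_ids_distinct(self, kb):
        t = run_session(kb, {"rapd": Y, "eye_pain": Y})
        qids = [s.question_id for s in t.steps]
        assert len(qids) == len(set(qids))

    def test_binocular_field_defect_tops_post_chiasmal(self, kb):
        answers = {"binocular_field_defect": Y, "monocular": N}
        t = run_session(kb, answers)
        assert t.final_differential.top_dx == "post_chiasmal"

    @pytest.mark.parametrize("seed", range(6))
    def test_final_probs_equal_joint_posterior_over_asked(self, seed):
        rng = np.random.default_rng(600 + seed)
        kb = make_random_kb(rng, n_dx=5, n_q=7)
        answers = random_answers(rng, kb)
        t = run_session(kb, answers)
        asked = {s.question_id: s.answer for s in t.steps}
        expected = joint_posterior_oracle(kb, asked)
        for dx in kb.diagnosis_ids:
            assert t.final_belief.probs[dx] == pytest.approx(expected[dx], abs=1e-12)

    def test_belief_always_normalized_along_the_way(self, kb):
        t = run_session(kb, {"red_reflex_absent": Y, "floaters": Y})
        for step in t.steps:
            assert sum(p for _, p in step.differential.ranked) == pytest.approx(1.0, abs=1e-9)


class TestEvidence:
    def test_no_answers_gives_empty_lists(self, kb):
        supports, refutes = evidence_for(kb, {}, "migraine")
        assert supports == [] and refutes == []

    def test_absent_red_reflex_supports_hemorrhage_refutes_neuritis(self, kb):
        answers = {"red_reflex_absent": Y}
        supports, _ = evidence_for(kb, answers, "vitreous_hemorrhage")
        assert [i.question_id for i in supports] == ["red_reflex_absent"]
        _, refutes = evidence_for(kb, answers, "optic_neuritis")
        assert [i.question_id for i in refutes] == ["red_reflex_absent"]

    def test_weights_sorted_descending_and_nonnegative(self, kb):
        answers = {"red_reflex_absent": Y, "floaters": Y, "rapd": N, "eye_pain": U}
        supports, refutes = evidence_for(kb, answers, "vitreous_hemorrhage")
        assert len(supports) + len(refutes) == 3  # UNKNOWN answers are skipped
        for group in (supports, refutes):
            weights = [i.weight for i in group]
            assert weights == sorted(weights, reverse=True)
            assert all(w >= 0 for w in weights)

    def test_unknown_diagnosis_rejected(self, kb):
        with pytest.raises(KeyError):
            evidence_for(kb, {}, "scurvy")
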