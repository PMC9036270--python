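"""Sequential Bayesian belief updating and greedy question selection.

The model is a naive-Bayes classifier over the 13 diagnoses: answers are
conditionally independent given the diagnosis, a YES to question *q* carries
likelihood ``p_yes(q, d)`` for diagnosis *d*, a NO carries ``1 - p_yes``,
and "don't know" carries likelihood 1 for every diagnosis (missing at
random), so it never moves the differential.

Question order is chosen greedily by *expected probability shift*: the
expected total-variation distance between the current belief and the
posterior after the answer, averaged over YES/NO weighted by their
predictive probabilities.  A question whose answer cannot move the belief
scores zero.  Sessions open with the fixed seed questions, then select
dynamically until the top diagnosis outweighs the runner-up by
``stop_ratio`` or the question budget is exhausted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Mapping

from .knowledge_base import KnowledgeBase

__all__ = [
    "AnswerValue",
    "BeliefState",
    "Differential",
    "SessionStep",
    "SessionTranscript",
    "Termination",
    "EvidenceDirection",
    "EvidenceItem",
    "initial_belief",
    "update",
    "predictive",
    "expected_shift",
    "next_question",
    "should_stop",
    "differential",
    "run_session",
    "evidence_for",
]

import math

_NORM_TOL = 1e-9


class AnswerValue(str, Enum):
    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"


class Termination(str, Enum):
    STOP_RULE = "STOP_RULE"
    MAX_QUESTIONS = "MAX_QUESTIONS"
    EXHAUSTED = "EXHAUSTED"
    USER = "USER"


class EvidenceDirection(str, Enum):
    SUPPORTS = "SUPPORTS"
    REFUTES = "REFUTES"


@dataclass(frozen=True)
class BeliefState:
    """Normalized probability vector over diagnoses plus the asked-question set."""

    probs: dict[str, float]
    asked: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        total = sum(self.probs.values())
        if abs(total - 1.0) > _NORM_TOL:
            raise ValueError(f"belief probabilities sum to {total!r}, not 1")
        if any(not 0.0 < p < 1.0 for p in self.probs.values()):
            raise ValueError("belief probabilities must lie strictly in (0, 1)")


@dataclass(frozen=True)
class Differential:
    """Full ranking of the vocabulary, descending by posterior."""

    ranked: tuple[tuple[str, float], ...]

    def top(self, k: int) -> tuple[str, ...]:
        return tuple(dx for dx, _ in self.ranked[:k])

    @property
    def top_dx(self) -> str:
        return self.ranked[0][0]


@dataclass(frozen=True)
class SessionStep:
    question_id: str
    answer: AnswerValue
    differential: Differential


@dataclass(frozen=True)
class SessionTranscript:
    steps: tuple[SessionStep, ...]
    terminated_by: Termination
    final_belief: BeliefState

    @property
    def final_differential(self) -> Differential:
        if self.steps:
            return self.steps[-1].differential
        return differential(self.final_belief)


@dataclass(frozen=True)
class EvidenceItem:
    question_id: str
    answer: AnswerValue
    direction: EvidenceDirection
    #: absolute natural-log likelihood ratio of the answer under the
    #: diagnosis versus under the prior-weighted average of the others
    weight: float


def initial_belief(kb: KnowledgeBase) -> BeliefState:
    """Fresh belief at the KB priors with no questions asked."""
    return BeliefState(probs=dict(kb.priors), asked=frozenset())


def _answer_likelihood(kb: KnowledgeBase, qid: str, answer: AnswerValue, dx: str) -> float:
    if answer is AnswerValue.UNKNOWN:
        return 1.0
    p = kb.p_yes(qid, dx)
    return p if answer is AnswerValue.YES else 1.0 - p


def _check_qid(kb: KnowledgeBase, qid: str) -> None:
    if qid not in kb.likelihoods:
        raise KeyError(f"unknown question id: {qid!r}")


def update(
    belief: BeliefState, kb: KnowledgeBase, qid: str, answer: AnswerValue
) -> BeliefState:
    """Absorb one answer by Bayes' rule and renormalize.

    UNKNOWN leaves the probabilities untouched (the question is still marked
    as asked); YES multiplies each diagnosis by ``p_yes(q, d)``, NO by
    ``1 - p_yes(q, d)``.
    """
    _check_qid(kb, qid)
    if qid in belief.asked:
        raise ValueError(f"question {qid!r} already asked")
    asked = belief.asked | {qid}
    if answer is AnswerValue.UNKNOWN:
        return BeliefState(probs=dict(belief.probs), asked=asked)
    post = {
        dx: p * _answer_likelihood(kb, qid, answer, dx)
        for dx, p in belief.probs.items()
    }
    total = sum(post.values())
    return BeliefState(probs={dx: p / total for dx, p in post.items()}, asked=asked)


def predictive(belief: BeliefState, kb: KnowledgeBase, qid: str) -> float:
    """Predictive probability of a YES answer under the current belief."""
    _check_qid(kb, qid)
    return sum(p * kb.p_yes(qid, dx) for dx, p in belief.probs.items())


def _total_variation(a: Mapping[str, float], b: Mapping[str, float]) -> float:
    return 0.5 * sum(abs(a[dx] - b[dx]) for dx in a)


def expected_shift(belief: BeliefState, kb: KnowledgeBase, qid: str) -> float:
    """Expected total-variation shift of the belief if ``qid`` were asked.

    ``E_a[TV(pre, post_a)]`` over YES/NO weighted by their predictive
    probabilities; zero exactly when the question cannot discriminate.
    """
    _check_qid(kb, qid)
    if qid in belief.asked:
        raise ValueError(f"question {qid!r} already asked")
    p_yes = predictive(belief, kb, qid)
    score = 0.0
    for answer, weight in ((AnswerValue.YES, p_yes), (AnswerValue.NO, 1.0 - p_yes)):
        post = update(belief, kb, qid, answer)
        score += weight * _total_variation(belief.probs, post.probs)
    return score


def next_question(belief: BeliefState, kb: KnowledgeBase) -> str | None:
    """The next question to ask, or None when every question has been asked.

    Unanswered seed questions come first in seed_rank order; after that, the
    unasked question with the highest expected shift, ties broken by
    lexicographic question id.
    """
    for q in kb.seed_questions():
        if q.id not in belief.asked:
            return q.id
    unasked = [qid for qid in kb.question_ids if qid not in belief.asked]
    if not unasked:
        return None
    return max(sorted(unasked), key=lambda qid: expected_shift(belief, kb, qid))


def should_stop(belief: BeliefState, kb: KnowledgeBase) -> bool:
    """Stop when the top diagnosis heavily outweighs the runner-up.

    True iff top/second posterior >= stop_ratio, the question budget is
    spent, or no unasked questions remain.
    """
    if len(belief.asked) >= kb.params.max_questions:
        return True
    if all(qid in belief.asked for qid in kb.question_ids):
        return True
    ranked = differential(belief, kb).ranked
    top, second = ranked[0][1], ranked[1][1]
    return top / second >= kb.params.stop_ratio


def differential(belief: BeliefState, kb: KnowledgeBase | None = None) -> Differential:
    """Rank the full vocabulary descending by posterior.

    Ties are broken by canonical diagnosis order, i.e. the order of the
    belief's probability mapping (which follows the KB's diagnosis list).
    """
    items = list(belief.probs.items())
    order = {dx: i for i, (dx, _) in enumerate(items)}
    ranked = sorted(items, key=lambda it: (-it[1], order[it[0]]))
    return Differential(ranked=tuple(ranked))


def _termination_reason(belief: BeliefState, kb: KnowledgeBase) -> Termination:
    ranked = differential(belief, kb).ranked
    if ranked[0][1] / ranked[1][1] >= kb.params.stop_ratio:
        return Termination.STOP_RULE
    if len(belief.asked) >= kb.params.max_questions:
        return Termination.MAX_QUESTIONS
    return Termination.EXHAUSTED


def run_session(
    kb: KnowledgeBase,
    answers: Mapping[str, AnswerValue] | Callable[[str], AnswerValue],
) -> SessionTranscript:
    """Run one full adaptive session against an answer source.

    ``answers`` maps question id -> answer; anything unanswered is treated
    as UNKNOWN.  Seed questions are asked first in seed_rank order (the
    opening survey is fixed regardless of confidence), then questions are
    selected greedily until :func:`should_stop` fires.
    """
    if callable(answers):
        lookup = answers
    else:
        lookup = lambda qid: answers.get(qid, AnswerValue.UNKNOWN)  # noqa: E731

    belief = initial_belief(kb)
    steps: list[SessionStep] = []

    for q in kb.seed_questions():
        answer = AnswerValue(lookup(q.id))
        belief = update(belief, kb, q.id, answer)
        steps.append(SessionStep(q.id, answer, differential(belief, kb)))

    while not should_stop(belief, kb):
        qid = next_question(belief, kb)
        if qid is None:  # pragma: no cover - guarded by should_stop
            break
        answer = AnswerValue(lookup(qid))
        belief = update(belief, kb, qid, answer)
        steps.append(SessionStep(qid, answer, differential(belief, kb)))

    return SessionTranscript(
        steps=tuple(steps),
        terminated_by=_termination_reason(belief, kb),
        final_belief=belief,
    )


def evidence_for(
    kb: KnowledgeBase,
    answers: Mapping[str, AnswerValue],
    dx: str,
) -> tuple[list[EvidenceItem], list[EvidenceItem]]:
    """Partition the answered questions into evidence for and against ``dx``.

    An answer supports the diagnosis when its likelihood under the diagnosis
    exceeds its prior-weighted average likelihood under all other diagnoses;
    the weight is the absolute log likelihood ratio of the two.  Returns
    ``(supports, refutes)``, each sorted by descending weight.
    """
    if dx not in kb.diagnosis_ids:
        raise KeyError(f"unknown diagnosis id: {dx!r}")
    priors = kb.priors
    other_mass = sum(p for d, p in priors.items() if d != dx)
    supports: list[EvidenceItem] = []
    refutes: list[EvidenceItem] = []
    for qid, answer in answers.items():
        answer = AnswerValue(answer)
        if answer is AnswerValue.UNKNOWN:
            continue
        _check_qid(kb, qid)
        lik_dx = _answer_likelihood(kb, qid, answer, dx)
        lik_other = (
            sum(
                priors[d] * _answer_likelihood(kb, qid, answer, d)
                for d in kb.diagnosis_ids
                if d != dx
            )
            / other_mass
        )
        weight = abs(math.log(lik_dx / lik_other))
        item = EvidenceItem(
            question_id=qid,
            answer=answer,
            direction=(
                EvidenceDirection.SUPPORTS
                if lik_dx > lik_other
                else EvidenceDirection.REFUTES
            ),
            weight=weight,
        )
        (supports if item.direction is EvidenceDirection.SUPPORTS else refutes).append(item)
    supports.sort(key=lambda it: -it.weight)
    refutes.sort(key=lambda it: -it.weight)
    return supports, refutes
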