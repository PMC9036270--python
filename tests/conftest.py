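"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from visiondx.bayes_engine import AnswerValue
from visiondx.knowledge_base import (
    ClusterLabel,
    DiagnosisLabel,
    EngineParams,
    KnowledgeBase,
    Question,
    UrgencyClass,
    builtin_kb,
)


@pytest.fixture(scope="session")
def kb() -> KnowledgeBase:
    return builtin_kb()


def make_random_kb(
    rng: np.random.Generator,
    n_dx: int = 5,
    n_q: int = 6,
    n_seeds: int = 3,
) -> KnowledgeBase:
    """A small random but structurally valid KB for property sweeps."""
    assert n_dx >= 2 and n_q >= n_seeds
    priors = rng.dirichlet(np.full(n_dx, 2.0))
    priors = priors / priors.sum()
    clusters = [c for c in ClusterLabel if c is not ClusterLabel.OTHER]
    diagnoses = tuple(
        DiagnosisLabel(
            id=f"d{i}",
            display_name=f"diagnosis {i}",
            cluster=clusters[i % len(clusters)],
            urgency=UrgencyClass.URGENT if i % 2 == 0 else UrgencyClass.NON_URGENT,
            prior=float(priors[i]),
        )
        for i in range(n_dx)
    )
    questions = tuple(
        Question(
            id=f"q{i}",
            text=f"question {i}?",
            seed_rank=i + 1 if i < n_seeds else None,
        )
        for i in range(n_q)
    )
    likelihoods = {
        q.id: {d.id: float(rng.uniform(0.05, 0.95)) for d in diagnoses}
        for q in questions
    }
    return KnowledgeBase(
        schema_version=1,
        diagnoses=diagnoses,
        questions=questions,
        likelihoods=likelihoods,
        params=EngineParams(),
    )


def random_answers(
    rng: np.random.Generator, kb: KnowledgeBase, p_unknown: float = 0.2
) -> dict[str, AnswerValue]:
    out = {}
    for qid in kb.question_ids:
        u = rng.random()
        if u < p_unknown:
            out[qid] = AnswerValue.UNKNOWN
        elif u < 0.5 + p_unknown / 2:
            out[qid] = AnswerValue.YES
        else:
            out[qid] = AnswerValue.NO
    return out


def joint_posterior_oracle(
    kb: KnowledgeBase, answers: dict[str, AnswerValue]
) -> dict[str, float]:
    """Brute-force one-shot posterior: multiply all answer likelihoods, normalize once."""
    weights = {}
    for dx in kb.diagnosis_ids:
        w = kb.priors[dx]
        for qid, ans in answers.items():
            if ans is AnswerValue.YES:
                w *= kb.p_yes(qid, dx)
            elif ans is AnswerValue.NO:
                w *= 1.0 - kb.p_yes(qid, dx)
        weights[dx] = w
    total = sum(weights.values())
    return {dx: w / total for dx, w in weights.items()}


def binom_pmf(k: int, n: int, p: float) -> float:
    return math.comb(n, k) * p**k * (1.0 - p) ** (n - k)


def clopper_pearson_bisection_oracle(
    x: int, n: int, level: float = 0.95, tol: float = 1e-12
) -> tuple[float, float]:
    """Exact CI bounds found by bisection on binomial tail sums (fractions)."""
    alpha = 1.0 - level

    def upper_tail(p: float) -> float:  # P(X >= x | p)
        return sum(binom_pmf(k, n, p) for k in range(x, n + 1))

    def lower_tail(p: float) -> float:  # P(X <= x | p)
        return sum(binom_pmf(k, n, p) for k in range(0, x + 1))

    def bisect(f, target: float) -> float:
        # f monotone increasing in p for upper_tail, decreasing for lower_tail
        lo, hi = 0.0, 1.0
        increasing = f(1.0) >= f(0.0)
        for _ in range(200):
            mid = (lo + hi) / 2.0
            if (f(mid) < target) == increasing:
                lo = mid
            else:
                hi = mid
            if hi - lo < tol:
                break
        return (lo + hi) / 2.0

    lo_bound = 0.0 if x == 0 else bisect(upper_tail, alpha / 2.0)
    hi_bound = 1.0 if x == n else bisect(lower_tail, alpha / 2.0)
    return lo_bound, hi_bound
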