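"""Canonical study fixture and synthetic cohort generation.

Two kinds of test/evaluation data live here:

* :func:`canonical_study_fixture` reconstructs a deterministic 79-patient
  encounter table — gold diagnoses, referrer diagnoses, and per-patient
  ranked differentials — that simultaneously satisfies every published
  marginal count of the vision-loss diagnostic-accuracy study it models:
  the per-diagnosis case mix, the per-cluster referrer and top-1/2/3
  correctness counts, the urgent/non-urgent margins (54/25), the urgency
  confusion matrices of both the algorithm (tp=51, tn=19) and the referrer
  (tp=31, tn=21), and the referrer no-diagnosis structure (37 overall, 22
  among urgent cases, 19 of those 22 algorithm-correct).  The constraint
  system is under-determined at the level of individual patients; the
  solution shipped here is one canonical assignment, frozen so that every
  evaluation statistic is bit-reproducible.  A consistency self-check runs
  on every construction.

* :func:`generate_cohort` draws synthetic questionnaire cohorts from a
  knowledge base's own likelihoods, with configurable answer-flip noise and
  missingness — the sampling model the naive-Bayes engine assumes, which is
  what makes noise-free cohorts a calibration check rather than a clinical
  claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .bayes_engine import (
    AnswerValue,
    Differential,
    SessionTranscript,
    run_session,
)
from .knowledge_base import OTHER, KnowledgeBase, UrgencyClass, builtin_kb
from .evaluation import EncounterRecord
from .triage import urgency_of

__all__ = [
    "CohortParams",
    "StudyFixture",
    "canonical_study_fixture",
    "generate_cohort",
    "simulate_sessions",
]

# Shorthand for the canonical diagnosis ids.
_ON = "optic_neuritis"
_ONC = "optic_nerve_compression"
_NAION = "naion_brao_bvo"
_CRAO = "crao"
_CVO = "cvo"
_TA = "temporal_arteritis"
_MAC = "other_macular"
_PR = "peripheral_retinal"
_FLT = "floaters_pvd"
_VH = "vitreous_hemorrhage"
_LENS = "lens_cornea"
_MIG = "migraine"
_PC = "post_chiasmal"

_Y, _N = AnswerValue.YES, AnswerValue.NO

# One entry per homogeneous patient group: (count, gold diagnoses, referrer
# diagnosis ("gold" = concordant, None = no diagnosis attempted), diagnoses
# ranked above the gold one in the algorithm differential (3+ entries push
# the gold diagnosis out of the top three), optional forced top diagnosis
# for dual-gold records, and fixed questionnaire answers for the cases whose
# error narratives pin them down).
_GROUPS: tuple[dict, ...] = (
    # --- Peripheral retinopathy/vitreous, urgent (23 cases) ---------------
    dict(n=5, gold=(_VH,), ref="gold"),
    dict(n=3, gold=(_PR,), ref="gold"),
    dict(n=1, gold=(_PR, _VH), ref=_PR, top=_PR),
    dict(n=2, gold=(_VH,), ref="gold", lead=(_FLT,)),
    dict(n=2, gold=(_VH,), ref=None),
    dict(n=4, gold=(_PR,), ref=None),
    dict(n=1, gold=(_PR, _VH), ref=None, top=_VH),
    # Older patient, RAPD never assessed: worst-case optic-nerve differential
    # over a longstanding retinal detachment.
    dict(
        n=1, gold=(_PR,), ref=None, lead=(_NAION, _TA, _MAC),
        answers={"age_over_50": _Y, "sudden_onset": _Y},
    ),
    dict(n=1, gold=(_VH,), ref=_PR),
    dict(n=1, gold=(_PR,), ref=_VH),
    dict(n=1, gold=(_VH,), ref=_FLT, lead=(_PR,)),
    dict(n=1, gold=(_PR,), ref=_CRAO, lead=(_FLT, _MAC)),
    # --- Vitreous floaters/PVD, non-urgent (5 cases) ----------------------
    dict(n=3, gold=(_FLT,), ref="gold"),
    dict(n=1, gold=(_FLT,), ref=None, lead=(_VH,)),
    # Referred as "floaters" (symptom only) but the questionnaire denied
    # flashes and floaters, so the differential never reaches the gold.
    dict(
        n=1, gold=(_FLT,), ref=None, lead=(_MAC, _LENS, _MIG),
        answers={"flashes": _N, "floaters": _N},
    ),
    # --- Optic nerve/circulation, urgent (28 cases) -----------------------
    dict(n=3, gold=(_NAION,), ref="gold"),
    dict(n=1, gold=(_ON,), ref="gold"),
    dict(n=1, gold=(_ONC,), ref="gold"),
    dict(n=1, gold=(_TA,), ref="gold"),
    dict(n=1, gold=(_CVO,), ref="gold"),
    dict(n=3, gold=(_NAION,), ref=None),
    dict(n=3, gold=(_ONC,), ref=None),
    dict(n=2, gold=(_ON,), ref=None),
    dict(n=1, gold=(_CVO,), ref=None),
    dict(n=1, gold=(_CRAO,), ref=None),
    dict(n=1, gold=(_TA,), ref=None),
    dict(n=1, gold=(_NAION,), ref=_CRAO),
    dict(n=1, gold=(_CVO,), ref="gold", lead=(_NAION,)),
    dict(n=1, gold=(_TA,), ref="gold", lead=(_NAION,)),
    dict(n=1, gold=(_NAION,), ref=_PC, lead=(_CVO,)),
    dict(n=1, gold=(_CRAO,), ref=_PR, lead=(_NAION,)),
    # Under-50 idiopathic branch artery occlusion: the engine correctly
    # prefers optic neuritis/compression in a young, non-vasculopathic eye.
    dict(
        n=1, gold=(_NAION,), ref=None, lead=(_ON, _ONC, _MIG),
        answers={"age_over_50": _N, "vascular_risk": _N},
    ),
    # "No red reflex" on the questionnaire: the engine reads vitreous
    # hemorrhage and demotes optic nerve/circulation causes.
    dict(
        n=2, gold=(_NAION,), ref=_PR, lead=(_VH, _PR, _LENS),
        answers={"red_reflex_absent": _Y},
    ),
    dict(
        n=1, gold=(_ON,), ref=_PC, lead=(_VH, _PR, _LENS),
        answers={"red_reflex_absent": _Y},
    ),
    dict(
        n=1, gold=(_ONC,), ref=_CRAO, lead=(_VH, _PR, _LENS),
        answers={"red_reflex_absent": _Y},
    ),
    # --- Other macular disease, non-urgent (8 cases) ----------------------
    dict(n=5, gold=(_MAC,), ref=None),
    dict(n=2, gold=(_MAC,), ref=_PR),
    dict(n=1, gold=(_MAC,), ref=_LENS),
    # --- Media (lens/cornea), non-urgent (6 cases) ------------------------
    dict(n=3, gold=(_LENS,), ref=None),
    dict(n=1, gold=(_LENS,), ref=_MIG),
    dict(n=1, gold=(_LENS,), ref=None, lead=(_VH,)),
    dict(n=1, gold=(_LENS,), ref=_PR, lead=(_MAC, _MIG)),
    # --- Migraine, non-urgent (6 cases) -----------------------------------
    dict(n=2, gold=(_MIG,), ref=None),
    dict(n=1, gold=(_MIG,), ref=None, lead=(_CRAO,)),
    dict(n=1, gold=(_MIG,), ref=None, lead=(_TA,)),
    dict(n=1, gold=(_MIG,), ref=_MAC, lead=(_PC,)),
    # Referrer reported a binocular field defect, so the engine tops
    # post-chiasmal disease over the eventual migraine diagnosis.
    dict(
        n=1, gold=(_MIG,), ref=_PC, lead=(_PC, _CRAO, _TA),
        answers={"binocular_field_defect": _Y},
    ),
    # --- Post-chiasmal disease, urgent (2 cases) --------------------------
    dict(n=1, gold=(_PC,), ref="gold"),
    dict(n=1, gold=(_PC,), ref=None),
    # --- Out-of-vocabulary (endophthalmitis), urgent (1 case) -------------
    dict(n=1, gold=(OTHER,), ref=None, lead=(_VH, _PR, _FLT)),
)

#: Geometric decay of the synthetic posteriors attached to fixture
#: differentials; any strictly decreasing profile works, the evaluation
#: statistics depend only on the ranking.
_POSTERIOR_DECAY = 0.7


@dataclass(frozen=True)
class StudyFixture:
    """The canonical cohort: records with attached differentials and flags."""

    records: tuple[EncounterRecord, ...]
    differentials: tuple[Differential, ...]

    @property
    def algorithm_flags(self) -> tuple[UrgencyClass, ...]:
        kb = builtin_kb()
        return tuple(urgency_of(d.top_dx, kb) for d in self.differentials)

    def diffs_by_patient(self) -> dict[str, Differential]:
        return {
            r.patient_id: d for r, d in zip(self.records, self.differentials)
        }


def _synthetic_differential(ranking: Sequence[str]) -> Differential:
    weights = np.array([_POSTERIOR_DECAY**i for i in range(len(ranking))])
    posts = weights / weights.sum()
    return Differential(
        ranked=tuple((dx, float(p)) for dx, p in zip(ranking, posts))
    )


def _expand_groups(kb: KnowledgeBase) -> tuple[list[EncounterRecord], list[Differential]]:
    canonical = kb.diagnosis_ids
    records: list[EncounterRecord] = []
    diffs: list[Differential] = []
    pid = 0
    for group in _GROUPS:
        gold = tuple(group["gold"])
        lead = tuple(group.get("lead", ()))
        top = group.get("top")
        answers = dict(group.get("answers", {}))
        for _ in range(group["n"]):
            pid += 1
            patient = f"P{pid:03d}"
            ref = group["ref"]
            if ref == "gold":
                ref = gold[0]
            head = list(lead)
            if top is not None:
                head.append(top)
            elif gold[0] != OTHER:
                head.append(gold[0])
            ranking = head + [dx for dx in canonical if dx not in head]
            records.append(
                EncounterRecord(
                    patient_id=patient,
                    answers=answers,
                    gold=frozenset(gold),
                    referrer_dx=ref,
                )
            )
            diffs.append(_synthetic_differential(ranking))
    return records, diffs


def _self_check(records: Sequence[EncounterRecord], diffs: Sequence[Differential], kb: KnowledgeBase) -> None:
    """Verify every published margin the fixture is required to reproduce."""
    from . import evaluation as ev  # local import to avoid a cycle at import time

    def require(cond: bool, msg: str) -> None:
        if not cond:
            raise AssertionError(f"canonical fixture inconsistent: {msg}")

    require(len(records) == 79, f"{len(records)} records, expected 79")

    # Per-diagnosis gold counts (dual-gold cases count under both labels).
    gold_counts: dict[str, int] = {}
    for r in records:
        for dx in r.gold:
            gold_counts[dx] = gold_counts.get(dx, 0) + 1
    expected_gold = {
        _VH: 13, _PR: 12, _NAION: 11, _MAC: 8, _LENS: 6, _FLT: 5, _MIG: 6,
        _CVO: 3, _ON: 4, _CRAO: 2, _TA: 3, _ONC: 5, _PC: 2, OTHER: 1,
    }
    require(gold_counts == expected_gold, f"gold counts {gold_counts}")
    require(sum(len(r.gold) == 2 for r in records) == 2, "dual-gold count != 2")

    # Urgency margins.
    urgent = [r for r in records if ev.gold_urgency(r, kb) is UrgencyClass.URGENT]
    require(len(urgent) == 54, f"{len(urgent)} urgent cases, expected 54")

    # Overall and per-cluster accuracy cells.
    require(ev.referrer_accuracy(records)[0] == 24, "referrer correct != 24")
    for k, want in ((1, 56), (2, 68), (3, 70)):
        require(ev.top_k_accuracy(records, diffs, k)[0] == want, f"top-{k} != {want}")
    from .knowledge_base import ClusterLabel as CL

    expected_cells = {
        CL.PERIPHERAL_VITREOUS: (28, 14, 21, 25, 26),
        CL.OPTIC_NERVE_CIRCULATION: (28, 9, 19, 23, 23),
        CL.OTHER_MACULAR: (8, 0, 8, 8, 8),
        CL.MEDIA: (6, 0, 4, 5, 6),
        CL.MIGRAINE: (6, 0, 2, 5, 5),
        CL.POST_CHIASMAL: (2, 1, 2, 2, 2),
        CL.OTHER: (1, 0, 0, 0, 0),
    }
    by_ref = ev.per_cluster_accuracy(records, None, None, kb)
    by_k = {k: ev.per_cluster_accuracy(records, diffs, k, kb) for k in (1, 2, 3)}
    for cl, (total, ref, t1, t2, t3) in expected_cells.items():
        require(by_ref[cl] == (ref, total), f"{cl.value} referrer cell")
        for k, want in ((1, t1), (2, t2), (3, t3)):
            require(by_k[k][cl] == (want, total), f"{cl.value} top-{k} cell")

    # Urgent-subset accuracies.
    u_idx = [i for i, r in enumerate(records) if ev.gold_urgency(r, kb) is UrgencyClass.URGENT]
    u_recs = [records[i] for i in u_idx]
    u_diffs = [diffs[i] for i in u_idx]
    require(ev.referrer_accuracy(u_recs)[0] == 21, "urgent referrer correct != 21")
    for k, want in ((1, 39), (2, 46), (3, 47)):
        require(ev.top_k_accuracy(u_recs, u_diffs, k)[0] == want, f"urgent top-{k} != {want}")
    n_idx = [i for i in range(len(records)) if i not in set(u_idx)]
    require(
        ev.top_k_accuracy([records[i] for i in n_idx], [diffs[i] for i in n_idx], 1)[0] == 17,
        "non-urgent top-1 != 17",
    )

    # Urgency confusion matrices.
    algo_flags = [urgency_of(d.top_dx, kb) for d in diffs]
    cm = ev.urgency_confusion(records, algo_flags, kb)
    require((cm.tp, cm.fn, cm.tn, cm.fp) == (51, 3, 19, 6), f"algorithm confusion {cm}")
    ref_flags = [ev.referrer_urgency_flag(r, kb) for r in records]
    cm = ev.urgency_confusion(records, ref_flags, kb)
    require((cm.tp, cm.fn, cm.tn, cm.fp) == (31, 23, 21, 4), f"referrer confusion {cm}")

    # Referrer no-diagnosis structure.
    no_dx = [r for r in records if r.referrer_dx is None]
    require(len(no_dx) == 37, f"{len(no_dx)} no-diagnosis referrals, expected 37")
    u_nodx = [
        (r, d) for r, d in zip(records, diffs)
        if r.referrer_dx is None and ev.gold_urgency(r, kb) is UrgencyClass.URGENT
    ]
    require(len(u_nodx) == 22, "urgent no-diagnosis referrals != 22")
    require(
        sum(bool(r.gold & set(d.top(1))) for r, d in u_nodx) == 19,
        "algorithm top-1 correct among urgent no-diagnosis referrals != 19",
    )
    # Urgent cases missed by the referrer but solved by the algorithm.
    rescued = sum(
        bool(r.gold & set(d.top(1)))
        for r, d in zip(records, diffs)
        if ev.gold_urgency(r, kb) is UrgencyClass.URGENT
        and not (r.referrer_dx is not None and r.referrer_dx in r.gold)
    )
    require(rescued == 22, f"urgent referrer-missed, algorithm-correct = {rescued}, expected 22")


def canonical_study_fixture(kb: KnowledgeBase | None = None) -> StudyFixture:
    """The frozen 79-patient cohort with attached differentials.

    Deterministic; the margin self-check runs on every call.
    """
    kb = kb or builtin_kb()
    records, diffs = _expand_groups(kb)
    _self_check(records, diffs, kb)
    return StudyFixture(records=tuple(records), differentials=tuple(diffs))


# ---------------------------------------------------------------------------
# Synthetic cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortParams:
    """Sampling parameters for synthetic questionnaire cohorts.

    ``prevalence`` defaults to the knowledge base priors (the empirical case
    mix); ``flip_rate`` inverts a sampled yes/no answer, ``missing_rate``
    then blanks it to "don't know".
    """

    n: int
    seed: int
    flip_rate: float = 0.0
    missing_rate: float = 0.0
    prevalence: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("flip_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.prevalence is not None:
            total = sum(self.prevalence.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"prevalence sums to {total!r}, expected 1")


def generate_cohort(kb: KnowledgeBase, params: CohortParams) -> list[EncounterRecord]:
    """Sample a synthetic cohort from the KB's own answer likelihoods.

    For each record a gold diagnosis is drawn from the prevalence, each
    answer is YES with probability ``p_yes(q, gold)``, flipped with
    probability ``flip_rate``, then blanked to UNKNOWN with probability
    ``missing_rate``.  A pure function of ``(kb, params)``.
    """
    rng = np.random.default_rng(params.seed)
    prevalence = dict(params.prevalence) if params.prevalence else dict(kb.priors)
    dx_ids = list(prevalence)
    weights = np.array([prevalence[dx] for dx in dx_ids])
    weights = weights / weights.sum()
    qids = list(kb.question_ids)

    records = []
    for i in range(params.n):
        gold = dx_ids[int(rng.choice(len(dx_ids), p=weights))]
        answers: dict[str, AnswerValue] = {}
        for qid in qids:
            yes = rng.random() < kb.p_yes(qid, gold)
            if rng.random() < params.flip_rate:
                yes = not yes
            if rng.random() < params.missing_rate:
                answers[qid] = AnswerValue.UNKNOWN
            else:
                answers[qid] = AnswerValue.YES if yes else AnswerValue.NO
        records.append(
            EncounterRecord(
                patient_id=f"S{i + 1:04d}",
                answers=answers,
                gold=frozenset({gold}),
                referrer_dx=None,
            )
        )
    return records


def simulate_sessions(
    kb: KnowledgeBase, records: Sequence[EncounterRecord]
) -> tuple[list[SessionTranscript], list[Differential]]:
    """Run the adaptive engine over each record's answers.

    Each record acts as the answer source for one session (anything it does
    not answer is "don't know").  Deterministic.
    """
    transcripts = []
    diffs = []
    for rec in records:
        unknown_keys = set(rec.answers) - set(kb.question_ids)
        if unknown_keys:
            raise KeyError(
                f"{rec.patient_id}: answers for unknown questions {sorted(unknown_keys)}"
            )
        t = run_session(kb, dict(rec.answers))
        transcripts.append(t)
        diffs.append(t.final_differential)
    return transcripts, diffs
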