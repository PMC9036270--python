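"""Knowledge base for the acute vision loss differential.

The engine runs on a small structured knowledge base: a fixed vocabulary of
13 diagnoses (in a canonical order used for all tie-breaking), a set of
Yes/No/Don't-know questions, a dense table of answer likelihoods
``p(YES | diagnosis)``, anatomical cluster and urgency maps, and a handful
of engine parameters.  The KB is shipped as a YAML document with an explicit
schema version and can be round-tripped losslessly.
"""

from __future__ import annotations

import importlib.resources
from enum import Enum
from pathlib import Path


import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = [
    "OTHER",
    "UrgencyClass",
    "ClusterLabel",
    "DiagnosisLabel",
    "Question",
    "EngineParams",
    "KnowledgeBase",
    "KBValidationError",
    "load_kb",
    "save_kb",
    "loads_kb",
    "dumps_kb",
    "validate_kb",
    "builtin_kb",
]

#: Sentinel id for gold-standard diagnoses outside the 13-item vocabulary
#: (e.g. endophthalmitis).  It never appears in a differential.
OTHER = "OTHER"

_SCHEMA_VERSION = 1
_PRIOR_TOL = 1e-9


class UrgencyClass(str, Enum):
    """Binary triage class: does the top diagnosis need rapid referral?"""

    URGENT = "URGENT"
    NON_URGENT = "NON_URGENT"


class ClusterLabel(str, Enum):
    """Anatomical demarcation clusters along the visual axis, plus OTHER."""

    PERIPHERAL_VITREOUS = "PERIPHERAL_VITREOUS"
    OPTIC_NERVE_CIRCULATION = "OPTIC_NERVE_CIRCULATION"
    OTHER_MACULAR = "OTHER_MACULAR"
    MEDIA = "MEDIA"
    MIGRAINE = "MIGRAINE"
    POST_CHIASMAL = "POST_CHIASMAL"
    OTHER = "OTHER"


class DiagnosisLabel(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    id: str
    display_name: str
    cluster: ClusterLabel
    urgency: UrgencyClass
    prior: float = Field(gt=0.0, lt=1.0)


class Question(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    id: str
    text: str
    #: 1-based position among the fixed opening questions; None for questions
    #: selected dynamically by expected probability shift.
    seed_rank: int | None = Field(default=None, ge=1)


class EngineParams(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    #: Stop once top posterior / runner-up posterior reaches this ratio.
    stop_ratio: float = Field(default=5.0, gt=1.0)
    #: Hard cap on the number of questions asked in one session.
    max_questions: int = Field(default=15, ge=1)
    #: Clipping floor for answer likelihoods; forbids zero-probability
    #: lockout so one contradictory answer can never eliminate a diagnosis.
    epsilon: float = Field(default=0.01, gt=0.0, lt=0.5)
    #: Confidence level for exact binomial intervals in reports.
    ci_level: float = Field(default=0.95, gt=0.0, lt=1.0)


class KBValidationError(ValueError):
    """Raised by :func:`load_kb` when a KB document violates the schema."""


class KnowledgeBase(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    schema_version: int
    diagnoses: tuple[DiagnosisLabel, ...]
    questions: tuple[Question, ...]
    #: likelihoods[question id][diagnosis id] -> p(YES | diagnosis)
    likelihoods: dict[str, dict[str, float]]
    params: EngineParams = EngineParams()

    # -- convenience accessors -------------------------------------------

    @property
    def diagnosis_ids(self) -> tuple[str, ...]:
        """Diagnosis ids in canonical order (the global tie-break order)."""
        return tuple(d.id for d in self.diagnoses)

    @property
    def question_ids(self) -> tuple[str, ...]:
        return tuple(q.id for q in self.questions)

    @property
    def priors(self) -> dict[str, float]:
        return {d.id: d.prior for d in self.diagnoses}

    @property
    def cluster_map(self) -> dict[str, ClusterLabel]:
        return {d.id: d.cluster for d in self.diagnoses}

    @property
    def urgency_map(self) -> dict[str, UrgencyClass]:
        return {d.id: d.urgency for d in self.diagnoses}

    def seed_questions(self) -> list[Question]:
        """Seed questions sorted by seed_rank."""
        seeds = [q for q in self.questions if q.seed_rank is not None]
        return sorted(seeds, key=lambda q: q.seed_rank)

    def p_yes(self, qid: str, dx: str) -> float:
        """Clipped probability that the answer to ``qid`` is YES given ``dx``."""
        eps = self.params.epsilon
        return min(max(self.likelihoods[qid][dx], eps), 1.0 - eps)


def validate_kb(kb: KnowledgeBase) -> list[str]:
    """Check every structural invariant; return a list of human-readable issues.

    Reports rather than raises: an empty list means the KB is valid.
    """
    issues: list[str] = []
    if kb.schema_version != _SCHEMA_VERSION:
        issues.append(
            f"schema_version: expected {_SCHEMA_VERSION}, got {kb.schema_version}"
        )

    dx_ids = list(kb.diagnosis_ids)
    if len(dx_ids) != 13:
        issues.append(f"diagnoses: expected 13 labels, got {len(dx_ids)}")
    if len(set(dx_ids)) != len(dx_ids):
        issues.append("diagnoses: duplicate ids")
    if OTHER in dx_ids:
        issues.append(f"diagnoses: reserved id {OTHER!r} used as a diagnosis")
    for d in kb.diagnoses:
        if d.cluster is ClusterLabel.OTHER:
            issues.append(f"diagnosis {d.id}: mapped to the OTHER cluster")

    clusters = {d.cluster for d in kb.diagnoses}
    non_other = [c for c in ClusterLabel if c is not ClusterLabel.OTHER]
    missing = [c.value for c in non_other if c not in clusters]
    if missing:
        issues.append(f"cluster_map: clusters with no diagnosis: {missing}")

    prior_sum = sum(d.prior for d in kb.diagnoses)
    if abs(prior_sum - 1.0) > _PRIOR_TOL:
        issues.append(f"priors: sum to {prior_sum!r}, expected 1 within {_PRIOR_TOL}")

    q_ids = list(kb.question_ids)
    if len(set(q_ids)) != len(q_ids):
        issues.append("questions: duplicate ids")
    seed_ranks = sorted(q.seed_rank for q in kb.questions if q.seed_rank is not None)
    if not 3 <= len(seed_ranks) <= 4:
        issues.append(f"questions: expected 3-4 seed questions, got {len(seed_ranks)}")
    if seed_ranks != list(range(1, len(seed_ranks) + 1)):
        issues.append(f"questions: seed ranks {seed_ranks} not contiguous from 1")

    eps = kb.params.epsilon
    for qid in q_ids:
        row = kb.likelihoods.get(qid)
        if row is None:
            issues.append(f"likelihoods: no row for question {qid}")
            continue
        for dx in dx_ids:
            if dx not in row:
                issues.append(f"likelihoods[{qid}]: missing diagnosis {dx}")
        for dx, p in row.items():
            if dx not in dx_ids:
                issues.append(f"likelihoods[{qid}]: unknown diagnosis {dx}")
            elif not eps <= p <= 1.0 - eps:
                issues.append(
                    f"likelihoods[{qid}][{dx}]: p_yes={p} outside [{eps}, {1 - eps}]"
                )
    extra_rows = set(kb.likelihoods) - set(q_ids)
    if extra_rows:
        issues.append(f"likelihoods: rows for unknown questions {sorted(extra_rows)}")

    return issues


def _from_document(doc: object, *, source: str) -> KnowledgeBase:
    if not isinstance(doc, dict):
        raise KBValidationError(f"{source}: KB document must be a mapping")
    try:
        kb = KnowledgeBase.model_validate(doc)
    except ValidationError as exc:
        lines = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise KBValidationError(
            f"{source}: invalid KB document:\n  " + "\n  ".join(lines)
        ) from exc

    issues = validate_kb(kb)
    prior_issues = [i for i in issues if i.startswith("priors:")]
    if prior_issues:
        raise KBValidationError(f"{source}: {prior_issues[0]}")
    if issues:
        raise KBValidationError(f"{source}:\n  " + "\n  ".join(issues))
    return kb


def loads_kb(text: str, *, source: str = "<string>") -> KnowledgeBase:
    """Parse and validate a KB from YAML text."""
    return _from_document(yaml.safe_load(text), source=source)


def load_kb(path: str | Path) -> KnowledgeBase:
    """Load and validate a KB file.

    Raises :class:`KBValidationError` listing every failing field if the
    document does not satisfy the schema or the structural invariants.
    """
    path = Path(path)
    return loads_kb(path.read_text(), source=str(path))


def _to_document(kb: KnowledgeBase) -> dict:
    doc = kb.model_dump(mode="json")
    for q in doc["questions"]:
        if q["seed_rank"] is None:
            del q["seed_rank"]
    return doc


def dumps_kb(kb: KnowledgeBase) -> str:
    """Serialize a KB to YAML text (inverse of :func:`loads_kb`)."""
    return yaml.safe_dump(_to_document(kb), sort_keys=False)


def save_kb(kb: KnowledgeBase, path: str | Path) -> None:
    Path(path).write_text(dumps_kb(kb))


def builtin_kb() -> KnowledgeBase:
    """The illustrative knowledge base shipped with the package.

    Twenty-one history/examination questions (none requiring fundoscopy beyond
    the red reflex) over the 13-diagnosis vocabulary, with likelihoods chosen
    to encode the standard clinical associations.
    """
    text = (
        importlib.resources.files("visiondx.data")
        .joinpath("vision_loss_kb.yaml")
        .read_text()
    )
    return loads_kb(text, source="builtin")


def canonical_sort_key(kb: KnowledgeBase) -> dict[str, int]:
    """Map diagnosis id -> canonical position, for tie-breaking."""
    return {dx: i for i, dx in enumerate(kb.diagnosis_ids)}
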