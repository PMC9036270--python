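"""Anatomical clustering and urgency triage.

Each of the 13 diagnoses belongs to exactly one anatomical cluster and one
urgency class.  The urgent class comprises retinal tears/detachments,
vitreous hemorrhage, all six optic nerve/circulation diagnoses and
post-chiasmal disease — conditions needing rapid specialist referral —
while floaters/PVD, other macular disease, media problems and migraine are
non-urgent.  Out-of-vocabulary gold diagnoses (the OTHER sentinel, e.g.
endophthalmitis) are counted urgent: they represent vitreous pathology the
differential cannot name.

A case's predicted urgency is simply the urgency of the top-ranked
diagnosis in its differential.
"""

from __future__ import annotations

from dataclasses import dataclass

from .bayes_engine import Differential
from .knowledge_base import OTHER, ClusterLabel, KnowledgeBase, UrgencyClass

__all__ = ["UrgencyConfusion", "cluster_of", "urgency_of", "predicted_urgency"]


@dataclass(frozen=True)
class UrgencyConfusion:
    """2x2 confusion with URGENT as the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")


def cluster_of(dx: str, kb: KnowledgeBase) -> ClusterLabel:
    """Anatomical cluster of a diagnosis id (OTHER sentinel maps to OTHER)."""
    if dx == OTHER:
        return ClusterLabel.OTHER
    try:
        return kb.cluster_map[dx]
    except KeyError:
        raise KeyError(f"unmapped diagnosis id: {dx!r}") from None


def urgency_of(dx: str, kb: KnowledgeBase) -> UrgencyClass:
    """Urgency class of a diagnosis id (OTHER sentinel counts URGENT)."""
    if dx == OTHER:
        return UrgencyClass.URGENT
    try:
        return kb.urgency_map[dx]
    except KeyError:
        raise KeyError(f"unmapped diagnosis id: {dx!r}") from None


def predicted_urgency(diff: Differential, kb: KnowledgeBase) -> UrgencyClass:
    """Urgency flag implied by a differential: the top diagnosis's urgency."""
    if not diff.ranked:
        raise ValueError("empty differential")
    return urgency_of(diff.top_dx, kb)
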