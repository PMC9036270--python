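"""Diagnostic-accuracy statistics for ranked differentials.

Implements the evaluation surface of a diagnostic-accuracy study: top-k
accuracy of a ranked differential against a gold-standard diagnosis,
referrer accuracy (a referral without a diagnosis counts as incorrect),
per-cluster breakdowns, urgency confusion matrices, and sensitivity/
specificity with exact (Clopper-Pearson) binomial confidence intervals.

Conventions: percentages are reported to one decimal and CI bounds to the
nearest integer percent, both rounded half-up.  A record with two gold
diagnoses counts correct if either is matched and is assigned to the
peripheral retinopathy/vitreous cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import beta as _beta

from .bayes_engine import AnswerValue, Differential
from .knowledge_base import OTHER, ClusterLabel, KnowledgeBase, UrgencyClass
from .triage import UrgencyConfusion, cluster_of, urgency_of

__all__ = [
    "EncounterRecord",
    "ProportionCI",
    "ClusterCounts",
    "AccuracyReport",
    "top_k_accuracy",
    "referrer_accuracy",
    "per_cluster_accuracy",
    "urgency_confusion",
    "referrer_urgency_flag",
    "sens_spec",
    "clopper_pearson",
    "build_report",
    "render_report",
    "read_encounters",
    "write_encounters",
    "read_differentials",
    "write_differentials",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (so 0.5 -> 1, matching clinical reporting style)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _percent(count: int, total: int) -> float:
    return round_half_up(100.0 * count / total, 1) if total else 0.0


@dataclass(frozen=True)
class EncounterRecord:
    """One patient encounter: answers, gold diagnosis set, referrer diagnosis."""

    patient_id: str
    answers: Mapping[str, AnswerValue]
    gold: frozenset[str]
    referrer_dx: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.gold) <= 2:
            raise ValueError(
                f"{self.patient_id}: gold set must have 1 or 2 diagnoses, "
                f"got {len(self.gold)}"
            )


@dataclass(frozen=True)
class ProportionCI:
    """A binomial proportion with an exact two-sided confidence interval.

    ``point`` is in percent to one decimal; ``lo``/``hi`` are the unrounded
    percent bounds (use :meth:`rounded_bounds` for the printed form).
    """

    successes: int
    trials: int
    level: float
    point: float
    lo: float
    hi: float

    def rounded_bounds(self) -> tuple[int, int]:
        return int(round_half_up(self.lo)), int(round_half_up(self.hi))


def clopper_pearson(successes: int, trials: int, level: float = 0.95) -> ProportionCI:
    """Exact (Clopper-Pearson) two-sided binomial confidence interval.

    Uses the beta-quantile characterization: the lower bound is the
    ``alpha/2`` quantile of Beta(x, n-x+1), the upper the ``1-alpha/2``
    quantile of Beta(x+1, n-x), with lo=0 at x=0 and hi=100 at x=n.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError(f"successes={successes} outside [0, {trials}]")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    x, n = successes, trials
    lo = 0.0 if x == 0 else float(_beta.ppf(alpha / 2.0, x, n - x + 1))
    hi = 1.0 if x == n else float(_beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return ProportionCI(
        successes=x,
        trials=n,
        level=level,
        point=_percent(x, n),
        lo=100.0 * lo,
        hi=100.0 * hi,
    )


def _check_aligned(records: Sequence[EncounterRecord], other: Sequence, what: str) -> None:
    if len(records) != len(other):
        raise ValueError(
            f"misaligned inputs: {len(records)} records but {len(other)} {what}"
        )


def _is_correct(record: EncounterRecord, diff: Differential, k: int) -> bool:
    # OTHER never appears in a differential, so an out-of-vocabulary gold
    # diagnosis can never be matched.
    return bool(record.gold & set(diff.top(k)))


def top_k_accuracy(
    records: Sequence[EncounterRecord],
    diffs: Sequence[Differential],
    k: int,
) -> tuple[int, float]:
    """(count, percent) of records whose gold set intersects the top-k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    _check_aligned(records, diffs, "differentials")
    count = sum(_is_correct(r, d, k) for r, d in zip(records, diffs))
    return count, _percent(count, len(records))


def referrer_accuracy(records: Sequence[EncounterRecord]) -> tuple[int, float]:
    """(count, percent) of records where the referrer named a gold diagnosis.

    A referral with no attempted diagnosis is incorrect by definition.
    """
    count = sum(r.referrer_dx is not None and r.referrer_dx in r.gold for r in records)
    return count, _percent(count, len(records))


def record_cluster(record: EncounterRecord, kb: KnowledgeBase) -> ClusterLabel:
    """Cluster a record by its gold diagnosis.

    Dual-gold records (peripheral retinal issue + vitreous hemorrhage) land
    in the peripheral retinopathy/vitreous cluster.
    """
    if len(record.gold) > 1:
        return ClusterLabel.PERIPHERAL_VITREOUS
    return cluster_of(next(iter(record.gold)), kb)


def per_cluster_accuracy(
    records: Sequence[EncounterRecord],
    diffs: Sequence[Differential] | None,
    k: int | None,
    kb: KnowledgeBase,
) -> dict[ClusterLabel, tuple[int, int]]:
    """Per-cluster (correct, total) counts.

    With ``diffs``/``k`` given, correctness is top-k correctness; with
    ``diffs=None`` it is referrer correctness.  Clusters with no records are
    absent from the result.
    """
    if diffs is not None:
        _check_aligned(records, diffs, "differentials")
    out: dict[ClusterLabel, list[int]] = {}
    for i, rec in enumerate(records):
        cl = record_cluster(rec, kb)
        correct, total = out.setdefault(cl, [0, 0])
        if diffs is None:
            ok = rec.referrer_dx is not None and rec.referrer_dx in rec.gold
        else:
            ok = _is_correct(rec, diffs[i], k)
        out[cl] = [correct + ok, total + 1]
    return {cl: (c, t) for cl, (c, t) in out.items()}


def gold_urgency(record: EncounterRecord, kb: KnowledgeBase) -> UrgencyClass:
    """URGENT if any gold diagnosis is urgent."""
    if any(urgency_of(dx, kb) is UrgencyClass.URGENT for dx in record.gold):
        return UrgencyClass.URGENT
    return UrgencyClass.NON_URGENT


def referrer_urgency_flag(record: EncounterRecord, kb: KnowledgeBase) -> UrgencyClass:
    """Urgency implied by the referral: no diagnosis flags NON_URGENT."""
    if record.referrer_dx is None:
        return UrgencyClass.NON_URGENT
    return urgency_of(record.referrer_dx, kb)


def urgency_confusion(
    records: Sequence[EncounterRecord],
    flags: Sequence[UrgencyClass],
    kb: KnowledgeBase,
) -> UrgencyConfusion:
    """Tabulate predicted urgency flags against gold urgency."""
    _check_aligned(records, flags, "flags")
    tp = fn = tn = fp = 0
    for rec, flag in zip(records, flags):
        gold_urgent = gold_urgency(rec, kb) is UrgencyClass.URGENT
        flagged = flag is UrgencyClass.URGENT
        if gold_urgent:
            tp += flagged
            fn += not flagged
        else:
            fp += flagged
            tn += not flagged
    return UrgencyConfusion(tp=tp, fn=fn, tn=tn, fp=fp)


def sens_spec(
    cm: UrgencyConfusion, level: float = 0.95
) -> tuple[ProportionCI, ProportionCI]:
    """Sensitivity and specificity with exact CIs."""
    if cm.tp + cm.fn == 0:
        raise ValueError("no positive (urgent) cases: sensitivity undefined")
    if cm.tn + cm.fp == 0:
        raise ValueError("no negative (non-urgent) cases: specificity undefined")
    sens = clopper_pearson(cm.tp, cm.tp + cm.fn, level)
    spec = clopper_pearson(cm.tn, cm.tn + cm.fp, level)
    return sens, spec


# ---------------------------------------------------------------------------
# Aggregate report
# ---------------------------------------------------------------------------

_CLUSTER_TITLES = {
    ClusterLabel.PERIPHERAL_VITREOUS: "Peripheral Retinopathy/Vitreous",
    ClusterLabel.OPTIC_NERVE_CIRCULATION: "Optic Nerve/Circulation",
    ClusterLabel.OTHER_MACULAR: "Other Macular Disease",
    ClusterLabel.MEDIA: "Media",
    ClusterLabel.MIGRAINE: "Migraine",
    ClusterLabel.POST_CHIASMAL: "Post-Chiasmal",
    ClusterLabel.OTHER: "Other",
}


@dataclass(frozen=True)
class ClusterCounts:
    cluster: ClusterLabel
    total: int
    referrer: int
    top_k: dict[int, int]


@dataclass(frozen=True)
class AccuracyReport:
    n: int
    ks: tuple[int, ...]
    referrer_count: int
    referrer_pct: float
    top_k_counts: dict[int, int]
    top_k_pct: dict[int, float]
    clusters: tuple[ClusterCounts, ...]
    algo_confusion: UrgencyConfusion
    referrer_confusion: UrgencyConfusion
    algo_sens: ProportionCI
    algo_spec: ProportionCI
    referrer_sens: ProportionCI
    referrer_spec: ProportionCI


def build_report(
    records: Sequence[EncounterRecord],
    diffs: Sequence[Differential],
    kb: KnowledgeBase,
    ks: Iterable[int] = (1, 2, 3),
) -> AccuracyReport:
    """Compute the full accuracy/triage report for a cohort."""
    ks = tuple(sorted(set(int(k) for k in ks)))
    _check_aligned(records, diffs, "differentials")

    ref_count, ref_pct = referrer_accuracy(records)
    top_counts: dict[int, int] = {}
    top_pct: dict[int, float] = {}
    for k in ks:
        c, p = top_k_accuracy(records, diffs, k)
        top_counts[k], top_pct[k] = c, p

    by_cluster_ref = per_cluster_accuracy(records, None, None, kb)
    by_cluster_k = {k: per_cluster_accuracy(records, diffs, k, kb) for k in ks}
    clusters = []
    for cl in ClusterLabel:
        if cl not in by_cluster_ref:
            continue
        correct, total = by_cluster_ref[cl]
        clusters.append(
            ClusterCounts(
                cluster=cl,
                total=total,
                referrer=correct,
                top_k={k: by_cluster_k[k][cl][0] for k in ks},
            )
        )

    algo_flags = [urgency_of(d.top_dx, kb) for d in diffs]
    ref_flags = [referrer_urgency_flag(r, kb) for r in records]
    algo_cm = urgency_confusion(records, algo_flags, kb)
    ref_cm = urgency_confusion(records, ref_flags, kb)
    level = kb.params.ci_level
    algo_sens, algo_spec = sens_spec(algo_cm, level)
    ref_sens, ref_spec = sens_spec(ref_cm, level)

    return AccuracyReport(
        n=len(records),
        ks=ks,
        referrer_count=ref_count,
        referrer_pct=ref_pct,
        top_k_counts=top_counts,
        top_k_pct=top_pct,
        clusters=tuple(clusters),
        algo_confusion=algo_cm,
        referrer_confusion=ref_cm,
        algo_sens=algo_sens,
        algo_spec=algo_spec,
        referrer_sens=ref_sens,
        referrer_spec=ref_spec,
    )


def render_report(report: AccuracyReport) -> str:
    """Render a report as aligned plain text (cluster table + triage stats)."""
    ks = report.ks
    header = ["Diagnostic Cluster", "Referrer"] + [f"Top {k}" for k in ks]
    rows: list[list[str]] = []
    for cc in report.clusters:
        rows.append(
            [f"{_CLUSTER_TITLES[cc.cluster]} (n = {cc.total})", f"{cc.referrer}/{cc.total}"]
            + [f"{cc.top_k[k]}/{cc.total}" for k in ks]
        )
    rows.append(
        ["Total", f"{report.referrer_count}/{report.n}"]
        + [f"{report.top_k_counts[k]}/{report.n}" for k in ks]
    )
    rows.append(
        ["", f"{report.referrer_pct}%"] + [f"{report.top_k_pct[k]}%" for k in ks]
    )
    widths = [max(len(r[i]) for r in [header] + rows) for i in range(len(header))]
    lines = ["  ".join(h.ljust(w) for h, w in zip(header, widths))]
    lines += ["  ".join(c.ljust(w) for c, w in zip(row, widths)) for row in rows]

    def ci_line(label: str, ci: ProportionCI) -> str:
        lo, hi = ci.rounded_bounds()
        pct = int(100 * ci.level)
        return (
            f"{label}: {ci.point}% ({ci.successes}/{ci.trials}) "
            f"({pct}% CI: {lo}-{hi}%)"
        )

    lines += [
        "",
        "Urgency triage (URGENT = positive class)",
        ci_line("Algorithm sensitivity", report.algo_sens),
        ci_line("Algorithm specificity", report.algo_spec),
        ci_line("Referrer sensitivity", report.referrer_sens),
        ci_line("Referrer specificity", report.referrer_spec),
    ]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Encounter-table / differential-table I/O (tab-delimited text)
# ---------------------------------------------------------------------------

_GOLD_SEP = ";"


def write_encounters(
    records: Sequence[EncounterRecord],
    path: str | Path,
    kb: KnowledgeBase,
    header_comment: str | None = None,
) -> None:
    """Write an encounter table: patient_id, gold_dx, referrer_dx, q_<id>..."""
    qids = list(kb.question_ids)
    rows = []
    for rec in records:
        row: dict[str, str] = {
            "patient_id": rec.patient_id,
            "gold_dx": _GOLD_SEP.join(sorted(rec.gold)),
            "referrer_dx": rec.referrer_dx or "",
        }
        for qid in qids:
            ans = AnswerValue(rec.answers.get(qid, AnswerValue.UNKNOWN))
            row[f"q_{qid}"] = "" if ans is AnswerValue.UNKNOWN else ans.value
        rows.append(row)
    frame = pd.DataFrame(rows)
    _atomic_write_table(frame, path, header_comment)


def read_encounters(path: str | Path, kb: KnowledgeBase) -> list[EncounterRecord]:
    """Read an encounter table; empty answer cells mean "don't know"."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    required = {"patient_id", "gold_dx", "referrer_dx"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    q_cols = [c for c in frame.columns if c.startswith("q_")]
    unknown_q = [c for c in q_cols if c[2:] not in kb.question_ids]
    if unknown_q:
        raise ValueError(f"{path}: answer columns for unknown questions {unknown_q}")

    valid_dx = set(kb.diagnosis_ids) | {OTHER}
    records = []
    for i, row in frame.iterrows():
        rownum = i + 2  # 1-based, after the header line
        gold = frozenset(g for g in str(row["gold_dx"]).split(_GOLD_SEP) if g)
        if not gold or not gold <= valid_dx:
            raise ValueError(f"{path}: row {rownum}: bad gold_dx {row['gold_dx']!r}")
        ref = str(row["referrer_dx"]) or None
        if ref is not None and ref not in valid_dx:
            raise ValueError(f"{path}: row {rownum}: bad referrer_dx {ref!r}")
        answers = {}
        for col in q_cols:
            cell = str(row[col]).strip()
            if cell == "":
                cell = AnswerValue.UNKNOWN.value
            try:
                answers[col[2:]] = AnswerValue(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: row {rownum}: bad answer {cell!r} in {col}"
                ) from None
        records.append(
            EncounterRecord(
                patient_id=str(row["patient_id"]),
                answers=answers,
                gold=gold,
                referrer_dx=ref,
            )
        )
    return records


def write_differentials(
    diffs: Mapping[str, Differential],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write differentials in long form: patient_id, rank, diagnosis, posterior."""
    rows = [
        {
            "patient_id": pid,
            "rank": rank,
            "diagnosis": dx,
            "posterior": f"{post:.6f}",
        }
        for pid, diff in diffs.items()
        for rank, (dx, post) in enumerate(diff.ranked, start=1)
    ]
    _atomic_write_table(pd.DataFrame(rows), path, header_comment)


def read_differentials(path: str | Path) -> dict[str, Differential]:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    out: dict[str, Differential] = {}
    for pid, group in frame.groupby("patient_id", sort=False):
        group = group.sort_values("rank", key=lambda s: s.astype(int))
        out[str(pid)] = Differential(
            ranked=tuple(
                (str(r["diagnosis"]), float(r["posterior"]))
                for _, r in group.iterrows()
            )
        )
    return out


def _atomic_write_table(
    frame: pd.DataFrame, path: str | Path, header_comment: str | None
) -> None:
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    text = frame.to_csv(sep="\t", index=False)
    if header_comment:
        text = "".join(f"# {line}\n" for line in header_comment.splitlines()) + text
    tmp.write_text(text)
    tmp.replace(path)
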