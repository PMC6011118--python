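"""Cohort evaluation with the screening study's exact error taxonomy.

Three kinds of error are tracked. A *false positive* is a truly euploid
sample called trisomic; a *false negative* is a truly trisomic sample called
euploid; an *incorrectly identified* sample is trisomic but called trisomic
for the wrong chromosome. Incorrectly identified samples play a dual role:
they count as DETECTED for overall sensitivity (an abnormality was flagged)
while being a per-chromosome false negative for their true chromosome and a
per-chromosome false positive for the called one. Per-chromosome specificity
uses all samples whose truth is NOT that trisomy (euploid + other trisomies)
as its denominator. Percentages are rounded half-up to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

from .classify import (
    SampleCall,
    STATUS_EUPLOID,
    STATUS_NON_EVALUABLE,
    STATUS_NONINFORMATIVE,
    STATUS_TRISOMY,
    TRISOMY_STATUS,
)
from .genome import TARGET_CHROMOSOMES

_EXCLUDED = (STATUS_NONINFORMATIVE, STATUS_NON_EVALUABLE)
TRISOMY_LABELS = tuple(TRISOMY_STATUS.values())


def percent(numerator: int, denominator: int) -> float:
    """Half-up percentage to 2 decimals, as the study reports its metrics."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    frac = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ChromosomeConfusion:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def sensitivity_pct(self) -> float:
        return percent(self.tp, self.tp + self.fn)

    @property
    def specificity_pct(self) -> float:
        return percent(self.tn, self.fp + self.tn)


@dataclass(frozen=True)
class ConfusionSummary:
    per_chromosome: dict[str, ChromosomeConfusion]
    n_evaluated: int
    n_excluded: int
    n_euploid: int
    n_pathological: int
    n_detected: int
    n_false_negative: int
    n_false_positive: int
    n_incorrectly_identified: int

    @property
    def overall_sensitivity_pct(self) -> float:
        return percent(self.n_detected, self.n_pathological)

    @property
    def overall_specificity_pct(self) -> float:
        return percent(self.n_euploid - self.n_false_positive, self.n_euploid)

    def to_dict(self) -> dict:
        return {
            "per_chromosome": {
                c: {
                    "tp": cc.tp,
                    "fn": cc.fn,
                    "fp": cc.fp,
                    "tn": cc.tn,
                    "sensitivity_pct": cc.sensitivity_pct,
                    "specificity_pct": cc.specificity_pct,
                }
                for c, cc in self.per_chromosome.items()
            },
            "n_evaluated": self.n_evaluated,
            "n_excluded": self.n_excluded,
            "n_euploid": self.n_euploid,
            "n_pathological": self.n_pathological,
            "n_detected": self.n_detected,
            "n_false_negative": self.n_false_negative,
            "n_false_positive": self.n_false_positive,
            "n_incorrectly_identified": self.n_incorrectly_identified,
            "overall_sensitivity_pct": self.overall_sensitivity_pct,
            "overall_specificity_pct": self.overall_specificity_pct,
        }


def evaluate(
    calls: Sequence[SampleCall],
    truth: Mapping[str, str],
    targets: Sequence[str] = TARGET_CHROMOSOMES,
) -> ConfusionSummary:
    """Score calls against truth labels (euploid / trisomy13 / 18 / 21).

    Noninformative and non-evaluable calls are excluded from every metric and
    reported via ``n_excluded``. Sample-id sets must match exactly.
    """
    call_ids = {c.sample_id for c in calls}
    if len(call_ids) != len(calls):
        raise ValueError("duplicate sample ids in calls")
    if call_ids != set(truth):
        raise ValueError("sample ids in calls and truth do not match")

    kept = [c for c in calls if c.status not in _EXCLUDED]
    n_excluded = len(calls) - len(kept)
    if not kept:
        raise ValueError("no evaluable samples")
    for c in kept:
        if c.status != STATUS_EUPLOID and c.status not in STATUS_TRISOMY:
            raise ValueError(f"{c.sample_id}: unknown call status {c.status!r}")

    per_chrom: dict[str, ChromosomeConfusion] = {}
    for chrom in targets:
        status = TRISOMY_STATUS[chrom]
        tp = sum(1 for c in kept if truth[c.sample_id] == status and c.status == status)
        fn = sum(1 for c in kept if truth[c.sample_id] == status and c.status != status)
        fp = sum(1 for c in kept if truth[c.sample_id] != status and c.status == status)
        tn = sum(1 for c in kept if truth[c.sample_id] != status and c.status != status)
        per_chrom[chrom] = ChromosomeConfusion(tp, fn, fp, tn)

    n_euploid = sum(1 for c in kept if truth[c.sample_id] == STATUS_EUPLOID)
    pathological = [c for c in kept if truth[c.sample_id] in TRISOMY_LABELS]
    detected = [c for c in pathological if c.status in TRISOMY_LABELS]
    incorrectly = [c for c in detected if c.status != truth[c.sample_id]]
    false_neg = [c for c in pathological if c.status == STATUS_EUPLOID]
    false_pos = [
        c
        for c in kept
        if truth[c.sample_id] == STATUS_EUPLOID and c.status in TRISOMY_LABELS
    ]
    return ConfusionSummary(
        per_chromosome=per_chrom,
        n_evaluated=len(kept),
        n_excluded=n_excluded,
        n_euploid=n_euploid,
        n_pathological=len(pathological),
        n_detected=len(detected),
        n_false_negative=len(false_neg),
        n_false_positive=len(false_pos),
        n_incorrectly_identified=len(incorrectly),
    )


def expand_outcome_table(
    outcome_counts: Mapping[tuple[str, str], int]
) -> tuple[list[SampleCall], dict[str, str]]:
    """Materialize a published (truth, called) outcome table as calls + truth.

    *outcome_counts* maps ``(truth_label, called_label)`` to a number of
    samples; this lets an enumerated cohort summary (e.g. "11 euploid samples
    called trisomy 18") be run through :func:`evaluate` as a worked example
    of the bookkeeping semantics.
    """
    calls: list[SampleCall] = []
    truth: dict[str, str] = {}
    i = 0
    for (true_label, called_label), n in outcome_counts.items():
        if n < 0:
            raise ValueError("outcome counts must be nonnegative")
        for _ in range(n):
            i += 1
            sid = f"o{i:04d}"
            positives = (
                (STATUS_TRISOMY[called_label],)
                if called_label in STATUS_TRISOMY
                else ()
            )
            calls.append(SampleCall(sid, called_label, positives))
            truth[sid] = true_label
    return calls, truth
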