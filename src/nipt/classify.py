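"""ROC cut-off calibration and rule-based trisomy classification.

Cut-offs are derived per target chromosome and per score from a labelled
calibration cohort by sweeping every candidate threshold (midpoints between
adjacent sorted unique score values, plus ±∞) and keeping the one that
maximizes Youden's J = sensitivity + specificity − 1; a sample is positive
for a score when the score is strictly greater than its cut-off. The
combination rule (default: TR and FGR both above cut-off at the same time)
is selected on the calibration cohort as the rule with the fewest total
misclassifications.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genome import TARGET_CHROMOSOMES
from .scores import ScoreSet

STATUS_EUPLOID = "euploid"
STATUS_NONINFORMATIVE = "noninformative"
STATUS_NON_EVALUABLE = "non_evaluable"
TRISOMY_STATUS = {"chr13": "trisomy13", "chr18": "trisomy18", "chr21": "trisomy21"}
STATUS_TRISOMY = {v: k for k, v in TRISOMY_STATUS.items()}

#: Which scores must all exceed their cut-offs for each combination rule;
#: ANY_TWO is handled separately.
RULES: dict[str, tuple[str, ...]] = {
    "Z": ("z",),
    "TR": ("tr",),
    "FGR": ("fgr",),
    "TR_AND_FGR": ("tr", "fgr"),
    "Z_AND_TR": ("z", "tr"),
    "Z_AND_FGR": ("z", "fgr"),
    "ALL_THREE": ("z", "tr", "fgr"),
    "ANY_TWO": (),
}
DEFAULT_RULE = "TR_AND_FGR"


@dataclass(frozen=True)
class RocCutoff:
    cutoff: float
    sensitivity: float
    specificity: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass(frozen=True)
class CutoffSet:
    """Per-chromosome, per-score cut-offs plus the chosen combination rule."""

    cutoffs: dict[str, dict[str, float]]  # chrom -> score -> cutoff
    rule: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown combination rule {self.rule!r}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"cutoffs": self.cutoffs, "rule": self.rule, "provenance": self.provenance},
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CutoffSet":
        d = json.loads(Path(path).read_text())
        cutoffs = {
            c: {s: float(v) for s, v in per.items()} for c, per in d["cutoffs"].items()
        }
        return cls(cutoffs, str(d["rule"]), dict(d.get("provenance", {})))


@dataclass(frozen=True)
class SampleCall:
    sample_id: str
    status: str
    positives: tuple[str, ...]
    scores: ScoreSet | None = None


def roc_cutoff(scores: Sequence[float], labels: Sequence[bool]) -> RocCutoff:
    """Youden-optimal threshold for "positive = score > cutoff".

    Sweeps midpoints between adjacent sorted unique scores plus ±∞; ties on J
    break toward higher specificity, then toward the higher cut-off.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to fit a ROC cut-off")
    u = np.unique(s)
    candidates = np.concatenate(([-np.inf], (u[:-1] + u[1:]) / 2.0, [np.inf]))
    sens = (s[y][:, None] > candidates).mean(axis=0)
    spec = (s[~y][:, None] <= candidates).mean(axis=0)
    j = sens + spec - 1.0
    # lexicographic argmax: J, then specificity, then cutoff (all ascending
    # preference); np.lexsort sorts ascending so take the last index.
    best = np.lexsort((candidates, spec, j))[-1]
    return RocCutoff(float(candidates[best]), float(sens[best]), float(spec[best]))


def _positive_chromosomes(
    scores: ScoreSet, cutoffs: CutoffSet, targets: Sequence[str]
) -> tuple[str, ...]:
    positives = []
    for chrom in targets:
        if chrom not in cutoffs.cutoffs:
            raise KeyError(f"no cut-offs for target chromosome {chrom}")
        per = cutoffs.cutoffs[chrom]
        values = {"z": scores.z[chrom], "tr": scores.tr[chrom], "fgr": scores.fgr[chrom]}
        if cutoffs.rule == "ANY_TWO":
            fired = sum(values[k] > per[k] for k in ("z", "tr", "fgr")) >= 2
        else:
            fired = all(values[k] > per[k] for k in RULES[cutoffs.rule])
        if fired:
            positives.append(chrom)
    return tuple(positives)


def classify(
    scores: ScoreSet,
    cutoffs: CutoffSet,
    informative: bool = True,
    size_gate: bool | None = True,
    targets: Sequence[str] = TARGET_CHROMOSOMES,
) -> SampleCall:
    """Apply gates then the combination rule to one sample's scores.

    ``size_gate=None`` marks the size ratio as unmeasurable (non-evaluable);
    a failed gate or uninformative read count yields ``noninformative``. With
    several positive chromosomes the call is the one with the largest TR, the
    full positive set being retained for audit.
    """
    if size_gate is None:
        return SampleCall(scores.sample_id, STATUS_NON_EVALUABLE, ())
    if not informative or not size_gate:
        return SampleCall(scores.sample_id, STATUS_NONINFORMATIVE, ())
    positives = _positive_chromosomes(scores, cutoffs, targets)
    if not positives:
        return SampleCall(scores.sample_id, STATUS_EUPLOID, (), scores)
    called = max(positives, key=lambda c: scores.tr[c])
    return SampleCall(scores.sample_id, TRISOMY_STATUS[called], positives, scores)


def calibrate(
    score_sets: Sequence[ScoreSet],
    truth: Mapping[str, str],
    targets: Sequence[str] = TARGET_CHROMOSOMES,
    rules: Sequence[str] | None = None,
) -> CutoffSet:
    """Fit per-score ROC cut-offs and pick the best combination rule.

    *truth* maps sample_id to one of euploid/trisomy13/trisomy18/trisomy21.
    For each target chromosome the ROC cases are the samples with that
    trisomy and the controls are the euploid samples. Every candidate rule is
    then evaluated on the calibration cohort itself; the rule with the fewest
    misclassified samples wins, ties resolving to TR_AND_FGR.
    """
    rules = tuple(rules or RULES)
    labels = [truth[s.sample_id] for s in score_sets]
    cutoffs: dict[str, dict[str, float]] = {}
    for chrom in targets:
        case_status = TRISOMY_STATUS[chrom]
        mask = [lab in (case_status, STATUS_EUPLOID) for lab in labels]
        subset = [s for s, m in zip(score_sets, mask) if m]
        y = [truth[s.sample_id] == case_status for s in subset]
        if sum(y) < 1 or len(y) - sum(y) < 2:
            raise ValueError(
                f"{chrom}: calibration needs ≥1 case and ≥2 euploid controls"
            )
        cutoffs[chrom] = {
            "z": roc_cutoff([s.z[chrom] for s in subset], y).cutoff,
            "tr": roc_cutoff([s.tr[chrom] for s in subset], y).cutoff,
            "fgr": roc_cutoff([s.fgr[chrom] for s in subset], y).cutoff,
        }

    def errors(rule: str) -> int:
        cs = CutoffSet(cutoffs, rule)
        wrong = 0
        for s, lab in zip(score_sets, labels):
            call = classify(s, cs, targets=targets)
            wrong += call.status != lab
        return wrong

    by_rule = {rule: errors(rule) for rule in rules}
    best_count = min(by_rule.values())
    if DEFAULT_RULE in by_rule and by_rule[DEFAULT_RULE] == best_count:
        best_rule = DEFAULT_RULE
    else:
        best_rule = min(by_rule, key=lambda r: (by_rule[r], r))
    provenance = {
        "n_samples": len(score_sets),
        "n_cases": {c: labels.count(TRISOMY_STATUS[c]) for c in targets},
        "n_euploid": labels.count(STATUS_EUPLOID),
        "selection": "youden_j",
        "rule_errors": by_rule,
    }
    return CutoffSet(cutoffs, best_rule, provenance)
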