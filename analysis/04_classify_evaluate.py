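"""Classify the scored cohort with the calibrated cut-offs and evaluate.

Applies the selected combination rule (TR and FGR above cut-off at the same
time, per the calibration step) plus the read-count and size-ratio gates,
then scores calls against truth with the three-way error taxonomy (false
positive / false negative / incorrectly identified).
Outputs: results/calls.tsv, results/cohort_summary.json.
"""

import json

import pandas as pd

from nipt.classify import CutoffSet, classify
from nipt.evaluate import evaluate
from nipt.fetal_fraction import size_ratio
from nipt.alignments import informative
from nipt.scores import frame_to_scores

from common import RESULTS, cohort


def main() -> None:
    cutoffs = CutoffSet.from_json(RESULTS / "cutoffs.json")
    scored = {
        s.sample_id: s
        for s in frame_to_scores(pd.read_csv(RESULTS / "scores.tsv", sep="\t"))
    }
    manifest = pd.read_csv(RESULTS / "cohort_manifest.tsv", sep="\t")
    truth = dict(zip(manifest["sample_id"], manifest["truth_label"]))

    calls = []
    for s in cohort():
        ratio = size_ratio(s.lengths)
        ss = scored.get(s.sample_id)
        if ss is None:  # gated out before scoring
            from nipt.scores import ScoreSet

            ss = ScoreSet(s.sample_id, {}, {}, {}, ratio.size_ratio, s.counts.total_unique)
        calls.append(
            classify(
                ss, cutoffs,
                informative=informative(s.counts),
                size_gate=ratio.passes_gate,
            )
        )
    pd.DataFrame(
        [
            {"sample_id": c.sample_id, "status": c.status, "positives": ",".join(c.positives)}
            for c in calls
        ]
    ).to_csv(RESULTS / "calls.tsv", sep="\t", index=False)

    summary = evaluate(calls, truth)
    (RESULTS / "cohort_summary.json").write_text(json.dumps(summary.to_dict(), indent=2))
    print(
        f"evaluated {summary.n_evaluated} samples "
        f"({summary.n_excluded} noninformative excluded)"
    )
    print(
        f"overall: sensitivity {summary.overall_sensitivity_pct}%, "
        f"specificity {summary.overall_specificity_pct}% "
        f"({summary.n_false_positive} FP, {summary.n_false_negative} FN, "
        f"{summary.n_incorrectly_identified} incorrectly identified)"
    )
    for chrom, cc in summary.per_chromosome.items():
        print(
            f"  {chrom}: sensitivity {cc.sensitivity_pct}%, "
            f"specificity {cc.specificity_pct}% (TP {cc.tp}, FN {cc.fn}, FP {cc.fp})"
        )


if __name__ == "__main__":
    main()
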