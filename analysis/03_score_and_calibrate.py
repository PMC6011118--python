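"""Score the cohort (Z/TR/FGR) against a 2-sample euploid panel; calibrate cut-offs.

Mirrors the study protocol: two euploid reference pregnancies form the
panel; Z uses raw %GR while TR and FGR use GC-corrected counts (stratum
re-weighting over 0.5% GC strata); per-chromosome, per-score ROC cut-offs
maximize Youden's J on the labelled cohort (resubstitution), and every
combination rule is compared by total misclassifications.
Outputs: results/scores.tsv, results/panel.json, results/cutoffs.json.
"""

import warnings

import numpy as np

from nipt.classify import STATUS_EUPLOID, TRISOMY_STATUS, calibrate
from nipt.fetal_fraction import size_ratio
from nipt.alignments import informative
from nipt.scores import build_reference, score_sample, scores_to_frame
from nipt.synthetic import SimulationConfig, simulate_counts

from common import BIN_WIDTH, COHORT_SEED, RESULTS, cohort, genome


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    g = genome()
    ref_rng = np.random.default_rng([3, COHORT_SEED])
    refs = [
        simulate_counts(
            SimulationConfig(seed=int(ref_rng.integers(2**31)), n_reads=5_000_000),
            g, bin_width=BIN_WIDTH, sample_id=f"ref{i + 1:02d}",
        )[0]
        for i in range(2)
    ]
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="reference panel has only")
        panel = build_reference(refs, g)
    panel.to_json(RESULTS / "panel.json")

    scored, truth = [], {}
    n_skipped = 0
    for s in cohort():
        if not informative(s.counts):
            n_skipped += 1
            continue
        ratio = size_ratio(s.lengths)
        if not ratio.passes_gate:
            n_skipped += 1
            continue
        scored.append(
            score_sample(s.counts, panel, g, size_ratio=ratio.size_ratio)
        )
        truth[s.sample_id] = TRISOMY_STATUS.get(s.truth.trisomy, STATUS_EUPLOID)

    scores_to_frame(scored).to_csv(RESULTS / "scores.tsv", sep="\t", index=False)
    cutoffs = calibrate(scored, truth)
    cutoffs.to_json(RESULTS / "cutoffs.json")

    print(f"scored {len(scored)} informative samples ({n_skipped} gated out)")
    print(f"selected combination rule: {cutoffs.rule}")
    print("misclassifications per candidate rule on the calibration cohort:")
    for rule, err in sorted(cutoffs.provenance["rule_errors"].items(), key=lambda kv: kv[1]):
        print(f"  {rule:12s} {err}")
    for chrom, per in cutoffs.cutoffs.items():
        print(
            f"  {chrom}: z > {per['z']:.3f}, tr > {per['tr']:.5f}, fgr > {per['fgr']:.5f}"
        )


if __name__ == "__main__":
    main()
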