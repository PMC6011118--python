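"""Simulate the study-shaped cohort and write its manifest and count matrix.

217 maternal-plasma-like samples (159 euploid, 34 T21, 18 T18, 6 T13) with
per-sample fetal fraction and sequencing depth drawn from realistic ranges.
Outputs: results/cohort_manifest.tsv (sample, truth, ff, depth) and
results/cohort_counts.tsv (per-chromosome unique-read counts, wide).
"""

import pandas as pd

from nipt.classify import STATUS_EUPLOID, TRISOMY_STATUS

from common import RESULTS, cohort


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    samples = cohort()
    manifest = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "truth_label": [
                TRISOMY_STATUS.get(s.truth.trisomy, STATUS_EUPLOID) for s in samples
            ],
            "fetal_fraction": [round(s.truth.fetal_fraction, 4) for s in samples],
            "depth": [s.counts.total_unique for s in samples],
        }
    )
    manifest.to_csv(RESULTS / "cohort_manifest.tsv", sep="\t", index=False)
    counts = pd.DataFrame(
        [{"sample_id": s.sample_id, **s.counts.counts} for s in samples]
    )
    counts.to_csv(RESULTS / "cohort_counts.tsv", sep="\t", index=False)
    by_label = manifest["truth_label"].value_counts()
    print(f"simulated {len(samples)} samples: {by_label.to_dict()}")
    print(
        "fetal fraction "
        f"{manifest['fetal_fraction'].min():.3f}-{manifest['fetal_fraction'].max():.3f}, "
        f"depth {manifest['depth'].min():,}-{manifest['depth'].max():,} unique reads"
    )
    print(f"wrote {RESULTS / 'cohort_manifest.tsv'} and cohort_counts.tsv")


if __name__ == "__main__":
    main()
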