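"""Shared study-cohort configuration for the numbered analysis scripts.

Each script regenerates the same seeded synthetic cohort (cheap and exactly
reproducible) rather than passing bulky per-sample intermediates around; the
compact stage outputs land in ``results/``.
"""

from __future__ import annotations

from functools import lru_cache
from pathlib import Path

from nipt.genome import GenomeTable
from nipt.synthetic import CohortSample, simulate_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"

# Study-shaped cohort: 159 euploid, 34 T21, 18 T18, 6 T13 (217 samples),
# fetal fractions 4-20%, unique depths 1.2-9M reads, 1 Mb bins for GC work.
COHORT_SEED = 20180607
COHORT_SIZES = dict(n_euploid=159, n_t21=34, n_t18=18, n_t13=6)
FF_RANGE = (0.04, 0.20)
DEPTH_RANGE = (1_200_000, 9_000_000)
BIN_WIDTH = 1_000_000
N_FRAGMENTS = 20_000


@lru_cache(maxsize=1)
def genome() -> GenomeTable:
    return GenomeTable.hg19()


@lru_cache(maxsize=1)
def cohort() -> tuple[CohortSample, ...]:
    return tuple(
        simulate_cohort(
            **COHORT_SIZES,
            ff_range=FF_RANGE,
            depth_range=DEPTH_RANGE,
            seed=COHORT_SEED,
            genome=genome(),
            bin_width=BIN_WIDTH,
            n_fragments=N_FRAGMENTS,
        )
    )
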