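import warnings

import pytest

from nipt.genome import Chromosome, GenomeTable


@pytest.fixture(scope="session")
def genome() -> GenomeTable:
    return GenomeTable.hg19()


@pytest.fixture(scope="session")
def tiny_genome() -> GenomeTable:
    """Three small chromosomes: fast SAM writing and bin arithmetic."""
    return GenomeTable(
        [
            Chromosome("chr1", 1_000_000, 0.42),
            Chromosome("chr2", 600_000, 0.38),
            Chromosome("chr21", 400_000, 0.41),
        ]
    )


@pytest.fixture(autouse=True)
def _quiet_small_panel_warnings():
    """Small reference panels are deliberate in tests; silence the fragility warning."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="reference panel has only", category=UserWarning
        )
        yield


# The published outcome tables of the two mapper arms, as (truth, called) -> n.
# Cohort: 34 T21, 18 T18, 6 T13, 159 euploid.
TMAP_OUTCOMES = {
    ("trisomy21", "trisomy21"): 33,
    ("trisomy21", "trisomy18"): 1,  # incorrectly identified
    ("trisomy18", "trisomy18"): 16,
    ("trisomy18", "euploid"): 1,  # false negative
    ("trisomy18", "trisomy21"): 1,  # incorrectly identified
    ("trisomy13", "trisomy13"): 6,
    ("euploid", "euploid"): 148,
    ("euploid", "trisomy18"): 11,  # false positives
}

HPG_OUTCOMES = {
    ("trisomy21", "trisomy21"): 34,
    ("trisomy18", "trisomy18"): 18,
    ("trisomy13", "trisomy13"): 6,
    ("euploid", "euploid"): 154,
    ("euploid", "trisomy21"): 2,
    ("euploid", "trisomy18"): 2,
    ("euploid", "trisomy13"): 1,
}
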