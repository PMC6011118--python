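"""Read SAM/BAM alignments, filter to uniquely mapped reads, count per chromosome.

Counting the share of uniquely mapped reads per chromosome is the basic
measurement of shallow-WGS aneuploidy screening: a fetal trisomy inflates the
affected chromosome's share in maternal plasma in proportion to the fetal
fraction. "Uniquely mapped" is operationalized here as a primary, mapped
alignment with MAPQ at or above a threshold (default 1) — mappers encode
multi-mapping reads via secondary flags and/or MAPQ 0, and the threshold makes
either convention reachable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .genome import GenomeTable, DEFAULT_BIN_WIDTH

FLAG_UNMAPPED = 0x4
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800

#: Strict read-count threshold for an informative sample: the screening is
#: considered evaluable only with MORE than this many unique reads.
MIN_INFORMATIVE_READS = 1_000_000


@dataclass(frozen=True)
class FragmentRecord:
    """One aligned read.

    ``pos`` is the leftmost mapped position, 1-based as in SAM text (converted
    to 0-based internally for bin arithmetic). ``length`` is the cfDNA
    fragment size in bp: for single-end semiconductor reads the sequenced read
    spans the whole molecule, so the aligned query length is used; records
    flagged paired fall back to |template length|.
    """

    chrom: str | None
    pos: int
    length: int
    mapq: int
    is_unique: bool
    flags: int


@dataclass
class ChromosomeCounts:
    """Per-chromosome unique-read counts for one sample.

    ``counts`` values are integers for raw tallies and floats after GC
    correction. ``bin_counts``, when present, is a DataFrame with columns
    ``chrom, start, end, gc, count`` over non-overlapping half-open bins.
    """

    sample_id: str
    counts: dict[str, float]
    bin_counts: pd.DataFrame | None = None
    n_skipped: int = 0

    @property
    def total_unique(self) -> float:
        total = sum(self.counts.values())
        return int(total) if float(total).is_integer() else float(total)

    def percent(self, chrom: str) -> float:
        """This chromosome's share of counted reads, in percent (%GR)."""
        if chrom not in self.counts:
            raise KeyError(f"{chrom} not in counted chromosomes")
        total = self.total_unique
        if total <= 0:
            raise ValueError("zero total count; %GR undefined")
        return 100.0 * self.counts[chrom] / total

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"chrom": list(self.counts), "count": list(self.counts.values())}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, sample_id: str | None = None) -> "ChromosomeCounts":
        df = pd.read_csv(path, sep="\t")
        counts = {str(r.chrom): float(r.count) for r in df.itertuples()}
        if all(float(v).is_integer() for v in counts.values()):
            counts = {c: int(v) for c, v in counts.items()}
        return cls(sample_id or Path(path).stem, counts)


def read_alignments(
    path: str | Path, min_mapq: int = 1
) -> Iterator[FragmentRecord]:
    """Stream :class:`FragmentRecord` from a SAM/BAM file.

    One record is yielded per alignment line. ``is_unique`` is true for
    mapped, primary (not secondary/supplementary) records with
    ``mapq >= min_mapq``.
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for read in sam:
            mapped = not read.is_unmapped
            primary = not (read.is_secondary or read.is_supplementary)
            if mapped and read.is_paired and read.template_length:
                length = abs(read.template_length)
            else:
                length = read.infer_query_length() or read.query_length or 0
            yield FragmentRecord(
                chrom=read.reference_name if mapped else None,
                pos=(read.reference_start + 1) if mapped else 0,
                length=int(length),
                mapq=int(read.mapping_quality),
                is_unique=bool(mapped and primary and read.mapping_quality >= min_mapq),
                flags=int(read.flag),
            )


def count_unique(
    records: Iterable[FragmentRecord],
    genome: GenomeTable,
    with_bins: bool = False,
    bin_width: int = DEFAULT_BIN_WIDTH,
    include: Sequence[str] | None = None,
    sample_id: str = "sample",
) -> ChromosomeCounts:
    """Tally unique records per chromosome (and optionally per bin).

    Only chromosomes in *include* (default chr1..22 + chrX) contribute.
    Records on chromosomes present in the genome but excluded (e.g. chrY) are
    silently dropped; records on chromosomes absent from the genome table are
    skipped with a warning and counted in ``n_skipped``. Empty input yields
    all-zero counts.
    """
    include = tuple(include or genome.included())
    counts: dict[str, float] = {c: 0 for c in include}
    positions: dict[str, list[int]] = {c: [] for c in include} if with_bins else {}
    n_skipped = 0
    for rec in records:
        if not rec.is_unique or rec.chrom is None:
            continue
        if rec.chrom not in counts:
            if rec.chrom not in genome:
                n_skipped += 1
            continue
        counts[rec.chrom] += 1
        if with_bins:
            positions[rec.chrom].append(rec.pos - 1)  # to 0-based
    if n_skipped:
        warnings.warn(
            f"{sample_id}: skipped {n_skipped} unique records on chromosomes "
            "absent from the genome table",
            stacklevel=2,
        )
    bin_counts = None
    if with_bins:
        bins = genome.bins(bin_width, include)
        tallies = []
        for chrom in include:
            n_bins = int((bins["chrom"] == chrom).sum())
            pos = np.asarray(positions[chrom], dtype=np.int64)
            idx = np.minimum(pos // bin_width, n_bins - 1) if len(pos) else pos
            tallies.append(np.bincount(idx, minlength=n_bins))
        bin_counts = bins.copy()
        bin_counts["count"] = np.concatenate(tallies) if tallies else []
    return ChromosomeCounts(sample_id, counts, bin_counts, n_skipped)


def informative(counts: ChromosomeCounts, min_reads: int = MIN_INFORMATIVE_READS) -> bool:
    """True iff the sample has strictly more than *min_reads* unique reads."""
    return counts.total_unique > min_reads


def fragment_lengths(records: Iterable[FragmentRecord]) -> list[int]:
    """Fragment sizes of the uniquely mapped records, order-preserving."""
    return [r.length for r in records if r.is_unique]


def count_sam(
    path: str | Path,
    genome: GenomeTable,
    min_mapq: int = 1,
    with_bins: bool = False,
    bin_width: int = DEFAULT_BIN_WIDTH,
    include: Sequence[str] | None = None,
    sample_id: str | None = None,
) -> tuple[ChromosomeCounts, list[int]]:
    """Convenience: one pass over a SAM/BAM giving counts and fragment lengths."""
    sample_id = sample_id or Path(path).stem
    records = list(read_alignments(path, min_mapq=min_mapq))
    counts = count_unique(
        records, genome, with_bins=with_bins, bin_width=bin_width,
        include=include, sample_id=sample_id,
    )
    return counts, fragment_lengths(records)
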