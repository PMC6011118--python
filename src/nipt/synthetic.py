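"""Seeded generator of maternal-plasma-like sequencing data with known truth.

The study cohort behind this pipeline is not deposited, so every downstream
stage is exercised against synthetic samples that emulate the statistical
structure the method assumes:

* per-chromosome unique-read counts are multinomial over length-proportional
  base weights, with a GC-dependent multiplicative bias that is linear in
  chromosome (or bin) GC content;
* a fetal trisomy overrepresents the affected chromosome by ``1 + ff/2`` —
  the fetal compartment (fraction ``ff`` of cfDNA) carries three copies of
  that chromosome instead of two;
* fragment lengths are a two-component normal mixture in which the fetal
  component is shorter (defaults: maternal 166 ± 20 bp, fetal 143 ± 20 bp,
  truncated to [50, 400] bp), which is what makes the short/long size ratio
  rise with fetal fraction.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .alignments import ChromosomeCounts
from .genome import GenomeTable, chromosome_weights_from_mapping

TRISOMY_CHOICES = ("none", "chr13", "chr18", "chr21")

# Substream tags so counts / fragments / SAM layout draw independent randomness
# from one config seed.
_STREAM_COUNTS, _STREAM_FRAGMENTS, _STREAM_SAM = 0, 1, 2


@dataclass(frozen=True)
class FragmentModel:
    """Two-component fragment-length mixture (all values in bp)."""

    maternal_mean: float = 166.0
    maternal_sd: float = 20.0
    fetal_mean: float = 143.0
    fetal_sd: float = 20.0
    lo: int = 50
    hi: int = 400

    def __post_init__(self) -> None:
        if self.maternal_sd <= 0 or self.fetal_sd <= 0:
            raise ValueError("fragment model SDs must be positive")
        if not self.lo < self.hi:
            raise ValueError("truncation window must be nonempty")


@dataclass(frozen=True)
class GroundTruth:
    """Known simulation truth attached to each synthetic sample."""

    trisomy: str
    fetal_fraction: float

    @property
    def expected_overrepresentation(self) -> float:
        """Dosage factor of the affected chromosome: 1 + ff/2 (1 if euploid)."""
        if self.trisomy == "none":
            return 1.0
        return 1.0 + self.fetal_fraction / 2.0


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_reads: int = 5_000_000
    trisomy: str = "none"
    fetal_fraction: float = 0.10
    gc_bias_slope: float = 0.3
    fragment_model: FragmentModel = field(default_factory=FragmentModel)
    #: optional explicit base proportions; default: hg19 length-proportional
    chromosome_weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.trisomy not in TRISOMY_CHOICES:
            raise ValueError(f"unknown trisomy label {self.trisomy!r}")
        if not 0.0 <= self.fetal_fraction <= 1.0:
            raise ValueError("fetal_fraction must lie in [0, 1]")
        if self.n_reads < 0:
            raise ValueError("n_reads must be nonnegative")


def _resolve_weights(
    config: SimulationConfig, genome: GenomeTable, include: tuple[str, ...]
) -> np.ndarray:
    if config.chromosome_weights is not None:
        w = chromosome_weights_from_mapping(config.chromosome_weights, include)
        return np.array([w[c] for c in include])
    w = genome.weights(include)
    return np.array([w[c] for c in include])


def _chromosome_probs(
    config: SimulationConfig, genome: GenomeTable
) -> tuple[tuple[str, ...], np.ndarray]:
    """Per-chromosome draw probabilities: weight × GC bias × trisomy dosage."""
    include = genome.included()
    weights = _resolve_weights(config, genome, include)
    gc = np.array([genome[c].gc for c in include])
    bias = 1.0 + config.gc_bias_slope * (gc - genome.mean_gc(include))
    dosage = np.array(
        [config.fetal_fraction / 2.0 + 1.0 if c == config.trisomy else 1.0 for c in include]
    )
    p = weights * bias * dosage
    if np.any(p < 0) or p.sum() <= 0:
        raise ValueError("probabilities not normalizable (GC bias slope too extreme?)")
    return include, p / p.sum()


def simulate_counts(
    config: SimulationConfig,
    genome: GenomeTable | None = None,
    bin_width: int | None = None,
    sample_id: str = "sim",
) -> tuple[ChromosomeCounts, GroundTruth]:
    """Draw per-chromosome unique-read counts for one synthetic sample.

    With ``bin_width`` set, reads are drawn at bin resolution — bin
    probability ∝ (chromosome weight × bin length share) × GC bias at the
    bin's GC × trisomy dosage — and chromosome counts are bin sums, so the
    sample carries the ``bin_counts`` table that GC correction needs.
    """
    genome = genome or GenomeTable.hg19()
    rng = np.random.default_rng([_STREAM_COUNTS, config.seed])
    truth = GroundTruth(config.trisomy, config.fetal_fraction)
    include, p_chrom = _chromosome_probs(config, genome)

    if bin_width is None:
        draws = rng.multinomial(config.n_reads, p_chrom)
        counts = {c: int(n) for c, n in zip(include, draws)}
        return ChromosomeCounts(sample_id, counts), truth

    bins = genome.bins(bin_width, include)
    weights = _resolve_weights(config, genome, include)
    w_per_chrom = dict(zip(include, weights))
    chrom_len = {c: genome[c].length for c in include}
    mean_gc = genome.mean_gc(include)
    dosage = bins["chrom"].map(
        lambda c: config.fetal_fraction / 2.0 + 1.0 if c == config.trisomy else 1.0
    )
    length_share = (bins["end"] - bins["start"]) / bins["chrom"].map(chrom_len)
    bias = 1.0 + config.gc_bias_slope * (bins["gc"] - mean_gc)
    p = (bins["chrom"].map(w_per_chrom) * length_share * bias * dosage).to_numpy()
    if np.any(p < 0) or p.sum() <= 0:
        raise ValueError("probabilities not normalizable (GC bias slope too extreme?)")
    draws = rng.multinomial(config.n_reads, p / p.sum())
    bin_counts = bins.copy()
    bin_counts["count"] = draws
    counts = {
        c: int(n)
        for c, n in bin_counts.groupby("chrom", sort=False)["count"].sum().items()
    }
    counts = {c: counts.get(c, 0) for c in include}
    return ChromosomeCounts(sample_id, counts, bin_counts), truth


def simulate_fragments(config: SimulationConfig, n: int) -> np.ndarray:
    """Draw *n* fragment lengths (integer bp) from the maternal/fetal mixture.

    Each length comes from the fetal component with probability
    ``fetal_fraction``, else the maternal component; both normals are
    truncated to the model's [lo, hi] window by resampling and rounded to
    whole bp.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    fm = config.fragment_model
    rng = np.random.default_rng([_STREAM_FRAGMENTS, config.seed])
    fetal = rng.random(n) < config.fetal_fraction
    mean = np.where(fetal, fm.fetal_mean, fm.maternal_mean)
    sd = np.where(fetal, fm.fetal_sd, fm.maternal_sd)
    lengths = rng.normal(mean, sd)
    out = (lengths < fm.lo) | (lengths > fm.hi)
    while np.any(out):
        lengths[out] = rng.normal(mean[out], sd[out])
        out = (lengths < fm.lo) | (lengths > fm.hi)
    return np.rint(lengths).astype(int)


@dataclass(frozen=True)
class CohortSample:
    sample_id: str
    counts: ChromosomeCounts
    lengths: np.ndarray
    truth: GroundTruth


def simulate_cohort(
    n_euploid: int,
    n_t21: int,
    n_t18: int,
    n_t13: int,
    ff_range: tuple[float, float] = (0.04, 0.20),
    depth_range: tuple[int, int] = (1_200_000, 9_000_000),
    seed: int = 0,
    genome: GenomeTable | None = None,
    bin_width: int | None = None,
    n_fragments: int = 20_000,
    gc_bias_slope: float = 0.3,
    fragment_model: FragmentModel | None = None,
) -> list[CohortSample]:
    """Simulate a labelled cohort in randomized order, reproducible from *seed*.

    Per-sample fetal fraction and unique-read depth are drawn uniformly from
    the given ranges. Defaults emulate the study conditions: fetal fractions
    spanning the typical first/second-trimester 4–20% range and unique-read
    depths of roughly 1–9 M reads per sample.
    """
    for n in (n_euploid, n_t21, n_t18, n_t13):
        if n < 0:
            raise ValueError("cohort sizes must be nonnegative")
    if not (0 <= ff_range[0] <= ff_range[1] <= 1):
        raise ValueError(f"invalid fetal-fraction range {ff_range}")
    if not (0 <= depth_range[0] <= depth_range[1]):
        raise ValueError(f"invalid depth range {depth_range}")
    genome = genome or GenomeTable.hg19()
    fragment_model = fragment_model or FragmentModel()

    labels = (
        ["none"] * n_euploid + ["chr21"] * n_t21 + ["chr18"] * n_t18 + ["chr13"] * n_t13
    )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(labels))
    samples = []
    for i, idx in enumerate(order):
        ff = float(rng.uniform(*ff_range))
        depth = int(rng.integers(depth_range[0], depth_range[1] + 1))
        child_seed = int(rng.integers(2**31))
        config = SimulationConfig(
            seed=child_seed,
            n_reads=depth,
            trisomy=labels[idx],
            fetal_fraction=ff,
            gc_bias_slope=gc_bias_slope,
            fragment_model=fragment_model,
        )
        sample_id = f"s{i + 1:04d}"
        counts, truth = simulate_counts(
            config, genome, bin_width=bin_width, sample_id=sample_id
        )
        lengths = simulate_fragments(config, n_fragments)
        samples.append(CohortSample(sample_id, counts, lengths, truth))
    return samples


# ---------------------------------------------------------------------------
# SAM emission (lets the alignment stage be tested end-to-end)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulatedRead:
    """One SAM record to emit: placeholder bases, explicit flags and MAPQ."""

    chrom: str | None
    pos: int  # 0-based leftmost; ignored when unmapped
    length: int
    flag: int
    mapq: int


@dataclass(frozen=True)
class SamTruth:
    """Generator bookkeeping for a written SAM: the oracle for round-trips."""

    unique_counts: dict[str, int]
    unique_lengths: list[int]
    n_records: int


def write_sam(path: str | Path, reads: Sequence[SimulatedRead], genome: GenomeTable) -> None:
    """Write single-end SAM v1.6 with @HD/@SQ headers and placeholder bases."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": genome[name].length} for name in genome.names],
    }
    ref_id = {name: i for i, name in enumerate(genome.names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, read in enumerate(reads):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"read{i:08d}"
            a.flag = read.flag
            a.mapping_quality = read.mapq
            if read.flag & 0x4 or read.chrom is None:
                a.reference_id = -1
                a.reference_start = -1
            else:
                if read.chrom not in ref_id:
                    raise ValueError(f"unknown chromosome {read.chrom}")
                a.reference_id = ref_id[read.chrom]
                a.reference_start = read.pos
                a.cigartuples = [(0, read.length)]
            out.write(a)


def simulate_sam(
    config: SimulationConfig,
    path: str | Path,
    genome: GenomeTable | None = None,
    secondary_fraction: float = 0.0,
    low_mapq_fraction: float = 0.0,
    unmapped_fraction: float = 0.0,
    mapq_unique: int = 60,
    mapq_low: int = 0,
) -> SamTruth:
    """Simulate a sample and write it as SAM, returning the unique-read truth.

    Of the ``n_reads`` records, the given fractions are flagged secondary,
    demoted to ``mapq_low``, or marked unmapped (disjoint sets, in that
    order); the remainder are unique primary alignments at ``mapq_unique``.
    ``SamTruth`` records exactly what a correct unique-read counter must
    recover.
    """
    for frac in (secondary_fraction, low_mapq_fraction, unmapped_fraction):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    if secondary_fraction + low_mapq_fraction + unmapped_fraction > 1.0:
        raise ValueError("fractions must sum to at most 1")
    genome = genome or GenomeTable.hg19()
    counts, _ = simulate_counts(config, genome)
    lengths = simulate_fragments(config, config.n_reads)
    rng = np.random.default_rng([_STREAM_SAM, config.seed])

    chroms = np.repeat(
        list(counts.counts), [counts.counts[c] for c in counts.counts]
    )
    rng.shuffle(chroms)
    n = len(chroms)
    n_sec = int(round(secondary_fraction * n))
    n_low = int(round(low_mapq_fraction * n))
    n_unm = int(round(unmapped_fraction * n))
    role = np.array(["unique"] * n, dtype=object)
    role[:n_sec] = "secondary"
    role[n_sec : n_sec + n_low] = "low_mapq"
    role[n_sec + n_low : n_sec + n_low + n_unm] = "unmapped"
    rng.shuffle(role)

    reads: list[SimulatedRead] = []
    unique_counts = {c: 0 for c in counts.counts}
    unique_lengths: list[int] = []
    for chrom, r, length in zip(chroms, role, lengths):
        length = int(length)
        pos = int(rng.integers(0, max(genome[chrom].length - length, 1)))
        if r == "unmapped":
            reads.append(SimulatedRead(None, 0, length, 0x4, 0))
            continue
        flag = 0x100 if r == "secondary" else 0
        mapq = mapq_low if r == "low_mapq" else mapq_unique
        reads.append(SimulatedRead(chrom, pos, length, flag, mapq))
        if r == "unique":
            unique_counts[chrom] += 1
            unique_lengths.append(length)
    write_sam(path, reads, genome)
    return SamTruth(unique_counts, unique_lengths, n)
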