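"""Reference-genome bookkeeping: chromosome sizes, GC content, and fixed-width bins.

The pipeline never touches sequence itself — every stage downstream of the
mapper only needs, per chromosome, its length (to form expected read-count
proportions) and its GC fraction (to model and correct GC-dependent coverage
bias). A table for hg19/GRCh37 is bundled; any tab-separated file with
``chrom``, ``length`` and ``gc`` columns can be loaded in its place.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

AUTOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))
#: Chromosomes counted toward totals and %GR denominators. chrY is excluded:
#: maternal plasma is overwhelmingly maternal (female) DNA, and the targets
#: are autosomal trisomies. chrX is counted but never a classification target.
DEFAULT_INCLUDE: tuple[str, ...] = AUTOSOMES + ("chrX",)
TARGET_CHROMOSOMES: tuple[str, ...] = ("chr13", "chr18", "chr21")

DEFAULT_BIN_WIDTH = 50_000


@dataclass(frozen=True)
class Chromosome:
    """One reference chromosome: name, length in bp, global GC fraction."""

    name: str
    length: int
    gc: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.name}: length must be positive")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError(f"{self.name}: gc fraction {self.gc} outside [0, 1]")


class GenomeTable:
    """Per-chromosome lengths and GC fractions, with derived bins and weights."""

    def __init__(self, chromosomes: Iterable[Chromosome]):
        self._chroms: dict[str, Chromosome] = {}
        for c in chromosomes:
            if c.name in self._chroms:
                raise ValueError(f"duplicate chromosome {c.name}")
            self._chroms[c.name] = c
        if not self._chroms:
            raise ValueError("empty genome table")

    # -- basic access -------------------------------------------------------

    def __contains__(self, name: str) -> bool:
        return name in self._chroms

    def __getitem__(self, name: str) -> Chromosome:
        return self._chroms[name]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._chroms)

    def included(self) -> tuple[str, ...]:
        """Chromosomes in the default include-list that exist in this table."""
        return tuple(c for c in DEFAULT_INCLUDE if c in self._chroms)

    # -- derived quantities -------------------------------------------------

    def weights(self, include: Sequence[str] | None = None) -> dict[str, float]:
        """Length-proportional base proportions over *include*, summing to 1."""
        include = tuple(include or self.included())
        total = sum(self._chroms[c].length for c in include)
        return {c: self._chroms[c].length / total for c in include}

    def mean_gc(self, include: Sequence[str] | None = None) -> float:
        """Unweighted mean of chromosome GC fractions over *include*."""
        include = tuple(include or self.included())
        return float(np.mean([self._chroms[c].gc for c in include]))

    def bins(
        self,
        bin_width: int = DEFAULT_BIN_WIDTH,
        include: Sequence[str] | None = None,
        gc_sd: float = 0.04,
    ) -> pd.DataFrame:
        """Fixed-width bins with synthetic per-bin GC values.

        Coordinates are 0-based half-open ``[start, end)``; the terminal bin of
        each chromosome is short when the length is not a multiple of
        *bin_width* and is kept (flagged via its width).

        The bundled table carries chromosome-level GC only, so per-bin GC is
        *synthesized*: drawn once, deterministically per (chromosome,
        bin_width), from a normal centred on the chromosome's global GC with
        standard deviation *gc_sd*, clipped to [0.2, 0.7]. This emulates
        within-chromosome GC heterogeneity of roughly the observed magnitude;
        it does not reproduce the true GC landscape of any genome. Load a real
        bin table with :func:`load_bins` when one is available.
        """
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        include = tuple(include or self.included())
        frames = []
        for name in include:
            chrom = self._chroms[name]
            starts = np.arange(0, chrom.length, bin_width, dtype=np.int64)
            ends = np.minimum(starts + bin_width, chrom.length)
            rng = np.random.default_rng(zlib.crc32(f"{name}:{bin_width}".encode()))
            gc = np.clip(rng.normal(chrom.gc, gc_sd, size=len(starts)), 0.2, 0.7)
            frames.append(
                pd.DataFrame(
                    {"chrom": name, "start": starts, "end": ends, "gc": gc}
                )
            )
        return pd.concat(frames, ignore_index=True)

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeTable":
        df = pd.read_csv(path, sep="\t")
        required = {"chrom", "length", "gc"}
        if not required.issubset(df.columns):
            raise ValueError(f"genome table needs columns {sorted(required)}")
        return cls(
            Chromosome(str(r.chrom), int(r.length), float(r.gc))
            for r in df.itertuples()
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "chrom": self.names,
                "length": [self._chroms[c].length for c in self.names],
                "gc": [self._chroms[c].gc for c in self.names],
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def hg19(cls) -> "GenomeTable":
        """The bundled hg19/GRCh37 chromosome table (chr1..22, X, Y)."""
        ref = resources.files("nipt.data").joinpath("hg19_chromosomes.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


def load_bins(path: str | Path) -> pd.DataFrame:
    """Load a per-bin GC table (columns chrom, start, end, gc) from TSV."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "gc"}
    if not required.issubset(df.columns):
        raise ValueError(f"bin table needs columns {sorted(required)}")
    return df


def chromosome_weights_from_mapping(
    weights: Mapping[str, float], include: Sequence[str]
) -> dict[str, float]:
    """Validate an explicit per-chromosome weight mapping (sums to 1 ± 1e-9)."""
    missing = [c for c in include if c not in weights]
    if missing:
        raise ValueError(f"weights missing chromosomes: {missing}")
    w = {c: float(weights[c]) for c in include}
    if any(v < 0 for v in w.values()):
        raise ValueError("weights must be nonnegative")
    total = sum(w.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"weights sum to {total}, expected 1 ± 1e-9")
    return w
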