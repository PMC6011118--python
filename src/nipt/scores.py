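"""Chromosome-representation statistics: GC correction, Z score, TR, FGR.

All three statistics are functions of a sample's percent genomic
representation (%GR) — a chromosome's share of uniquely mapped reads over
chr1..22 + chrX — compared against a small euploid reference panel:

* **Z score** — standardized deviation of the *raw* %GR from the panel's
  mean/SD (no GC adjustment, deliberately).
* **TR (Trisomy Ratio)** — GC-corrected %GR divided by the panel's
  GC-corrected mean; ≈ 1 for euploid samples, ≈ 1 + ff/2 for a trisomy at
  fetal fraction ff, so ``2 × (TR − 1)`` doubles as a dosage-based
  fetal-fraction estimate.
* **FGR (Fractional Genomic Representation)** — the GC-corrected %GR itself,
  judged downstream against its own ROC cut-off rather than relative to the
  panel mean.

GC correction rescales binned counts by the inverse of the fitted
count-per-bp versus GC trend; the default fit is stratum re-weighting over
0.5%-wide GC strata (parameter-light, exactly the identity when there is no
bias), with LOESS and global-linear fits selectable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alignments import ChromosomeCounts
from .genome import GenomeTable, TARGET_CHROMOSOMES

GC_MODELS = ("strata", "loess", "linear", "none")
DEFAULT_STRATA_WIDTH = 0.005
MIN_CORRECTION_BINS = 20


class DegenerateReference(ValueError):
    """Reference spread is zero (or mean nonpositive): score undefined."""


@dataclass(frozen=True)
class ReferencePanel:
    """Euploid reference statistics: per-chromosome mean/SD of %GR.

    ``raw_*`` come from uncorrected counts (used by the Z score);
    ``corrected_*`` from GC-corrected counts (used by TR). SDs use the n−1
    denominator; with a two-sample panel that is |x1 − x2|/√2.
    """

    chromosomes: tuple[str, ...]
    raw_mean: dict[str, float]
    raw_sd: dict[str, float]
    corrected_mean: dict[str, float]
    corrected_sd: dict[str, float]
    n_reference: int
    gc_model: str

    def to_json(self, path: str | Path) -> None:
        payload = {
            "chromosomes": list(self.chromosomes),
            "raw_mean": self.raw_mean,
            "raw_sd": self.raw_sd,
            "corrected_mean": self.corrected_mean,
            "corrected_sd": self.corrected_sd,
            "n_reference": self.n_reference,
            "gc_model": self.gc_model,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferencePanel":
        d = json.loads(Path(path).read_text())
        return cls(
            tuple(d["chromosomes"]),
            {k: float(v) for k, v in d["raw_mean"].items()},
            {k: float(v) for k, v in d["raw_sd"].items()},
            {k: float(v) for k, v in d["corrected_mean"].items()},
            {k: float(v) for k, v in d["corrected_sd"].items()},
            int(d["n_reference"]),
            str(d["gc_model"]),
        )


@dataclass(frozen=True)
class ScoreSet:
    """Per-sample Z/TR/FGR for each target chromosome, plus carried metadata."""

    sample_id: str
    z: dict[str, float]
    tr: dict[str, float]
    fgr: dict[str, float]
    size_ratio: float | None
    total_unique: float


def percent_representation(counts: ChromosomeCounts, chrom: str) -> float:
    """%GR: 100 × counts[chrom] / total over included chromosomes."""
    return counts.percent(chrom)


def _fit_expected_rate(
    gc: np.ndarray,
    rate: np.ndarray,
    model: str,
    strata_width: float,
    loess_frac: float,
) -> np.ndarray:
    """Expected count-per-bp at each bin's GC under the chosen trend model."""
    if model == "strata":
        idx = np.floor(gc / strata_width).astype(int)
        strata = pd.Series(rate).groupby(idx).mean()
        nonzero = strata[strata > 0]
        if nonzero.empty:
            raise ValueError("all GC strata empty; cannot fit correction")
        keys = nonzero.index.to_numpy()

        def stratum_rate(i: int) -> float:
            v = strata.get(i, 0.0)
            if v > 0:
                return float(v)
            # empty/zero stratum: borrow the nearest stratum with signal
            return float(nonzero.iloc[int(np.argmin(np.abs(keys - i)))])

        return np.array([stratum_rate(int(i)) for i in idx])
    if model == "linear":
        coef = np.polyfit(gc, rate, 1)
        return np.polyval(coef, gc)
    if model == "loess":
        from statsmodels.nonparametric.smoothers_lowess import lowess

        fitted = lowess(rate, gc, frac=loess_frac, return_sorted=True)
        return np.interp(gc, fitted[:, 0], fitted[:, 1])
    raise ValueError(f"unknown GC model {model!r}")


def gc_correct(
    counts: ChromosomeCounts,
    genome: GenomeTable | None = None,
    model: str = "strata",
    strata_width: float = DEFAULT_STRATA_WIDTH,
    loess_frac: float = 0.3,
    min_bins: int = MIN_CORRECTION_BINS,
) -> ChromosomeCounts:
    """Rescale binned counts so the fitted count-vs-GC trend becomes flat.

    Each bin's count is multiplied by ``mean rate / fitted rate(gc)`` where
    rate is count per bp (normalizing by bin width keeps terminal short bins
    comparable); corrected chromosome counts are corrected-bin sums.
    """
    if model == "none":
        return counts
    if counts.bin_counts is None:
        raise ValueError("GC correction requires bin-level counts")
    bc = counts.bin_counts
    if int((bc["count"] > 0).sum()) < min_bins:
        raise ValueError(
            f"GC correction needs ≥{min_bins} bins with nonzero counts"
        )
    width = (bc["end"] - bc["start"]).to_numpy(dtype=float)
    rate = bc["count"].to_numpy(dtype=float) / width
    gc = bc["gc"].to_numpy(dtype=float)
    expected = _fit_expected_rate(gc, rate, model, strata_width, loess_frac)
    # guard against nonpositive fitted rates from the unconstrained fits
    expected = np.where(expected > 0, expected, rate.mean())
    factor = rate.mean() / expected
    corrected = bc.copy()
    corrected["count"] = bc["count"].to_numpy(dtype=float) * factor
    chrom_counts = corrected.groupby("chrom", sort=False)["count"].sum()
    new_counts = {c: float(chrom_counts.get(c, 0.0)) for c in counts.counts}
    return ChromosomeCounts(counts.sample_id, new_counts, corrected, counts.n_skipped)


def build_reference(
    samples: Sequence[ChromosomeCounts],
    genome: GenomeTable | None = None,
    gc_model: str = "strata",
    **gc_kwargs,
) -> ReferencePanel:
    """Summarize euploid reference samples into per-chromosome mean/SD of %GR.

    A panel smaller than 10 samples triggers a fragility warning (the
    original protocol used only two euploid pregnancies — reproducible, but
    the SD estimate is weak).
    """
    if len(samples) < 2:
        raise ValueError("reference panel needs at least 2 samples")
    if len(samples) < 10:
        warnings.warn(
            f"reference panel has only {len(samples)} samples; "
            "mean/SD estimates will be fragile",
            stacklevel=2,
        )
    chroms = tuple(samples[0].counts)
    if gc_model != "none" and any(s.bin_counts is None for s in samples):
        warnings.warn(
            "reference samples lack bin counts; GC-corrected panel statistics "
            "fall back to raw %GR",
            stacklevel=2,
        )
        gc_model = "none"
    raw = np.array([[s.percent(c) for c in chroms] for s in samples])
    if gc_model == "none":
        corr = raw
    else:
        corrected = [gc_correct(s, genome, model=gc_model, **gc_kwargs) for s in samples]
        corr = np.array([[s.percent(c) for c in chroms] for s in corrected])
    return ReferencePanel(
        chromosomes=chroms,
        raw_mean={c: float(m) for c, m in zip(chroms, raw.mean(axis=0))},
        raw_sd={c: float(s) for c, s in zip(chroms, raw.std(axis=0, ddof=1))},
        corrected_mean={c: float(m) for c, m in zip(chroms, corr.mean(axis=0))},
        corrected_sd={c: float(s) for c, s in zip(chroms, corr.std(axis=0, ddof=1))},
        n_reference=len(samples),
        gc_model=gc_model,
    )


def z_score(percent_gr: float, panel: ReferencePanel, chrom: str) -> float:
    """Standardized raw %GR: (sample − panel mean) / panel SD."""
    sd = panel.raw_sd[chrom]
    if sd <= 0:
        raise DegenerateReference(f"{chrom}: reference SD is zero; Z undefined")
    return (percent_gr - panel.raw_mean[chrom]) / sd


def trisomy_ratio(corrected_percent_gr: float, panel: ReferencePanel, chrom: str) -> float:
    """GC-corrected %GR relative to the panel's GC-corrected mean (≈1 euploid)."""
    mean = panel.corrected_mean[chrom]
    if mean <= 0:
        raise DegenerateReference(f"{chrom}: reference corrected mean is nonpositive")
    return corrected_percent_gr / mean


def fgr(corrected_counts: ChromosomeCounts, chrom: str) -> float:
    """Fractional Genomic Representation: the GC-corrected %GR itself."""
    return corrected_counts.percent(chrom)


def score_sample(
    counts: ChromosomeCounts,
    panel: ReferencePanel,
    genome: GenomeTable | None = None,
    size_ratio: float | None = None,
    targets: Sequence[str] = TARGET_CHROMOSOMES,
    gc_model: str | None = None,
    **gc_kwargs,
) -> ScoreSet:
    """Assemble Z/TR/FGR for the target chromosomes of one sample.

    The GC model defaults to the one the panel was built with; Z always uses
    raw %GR while TR and FGR use the corrected counts.
    """
    model = panel.gc_model if gc_model is None else gc_model
    corrected = (
        gc_correct(counts, genome, model=model, **gc_kwargs)
        if model != "none"
        else counts
    )
    z = {c: z_score(counts.percent(c), panel, c) for c in targets}
    tr = {c: trisomy_ratio(corrected.percent(c), panel, c) for c in targets}
    f = {c: fgr(corrected, c) for c in targets}
    return ScoreSet(
        sample_id=counts.sample_id,
        z=z,
        tr=tr,
        fgr=f,
        size_ratio=size_ratio,
        total_unique=counts.total_unique,
    )


# -- tabular (de)serialization ----------------------------------------------


def scores_to_frame(score_sets: Sequence[ScoreSet]) -> pd.DataFrame:
    """Wide per-sample table: z/tr/fgr per target chromosome + metadata."""
    rows = []
    for s in score_sets:
        row: dict[str, object] = {
            "sample_id": s.sample_id,
            "total_unique": s.total_unique,
            "size_ratio": s.size_ratio,
        }
        for chrom in s.z:
            suffix = chrom.removeprefix("chr")
            row[f"z{suffix}"] = s.z[chrom]
            row[f"tr{suffix}"] = s.tr[chrom]
            row[f"fgr{suffix}"] = s.fgr[chrom]
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_scores(df: pd.DataFrame, targets: Sequence[str] = TARGET_CHROMOSOMES) -> list[ScoreSet]:
    out = []
    for r in df.itertuples():
        z, tr, f = {}, {}, {}
        for chrom in targets:
            suffix = chrom.removeprefix("chr")
            z[chrom] = float(getattr(r, f"z{suffix}"))
            tr[chrom] = float(getattr(r, f"tr{suffix}"))
            f[chrom] = float(getattr(r, f"fgr{suffix}"))
        ratio = getattr(r, "size_ratio", None)
        ratio = None if ratio is None or pd.isna(ratio) else float(ratio)
        out.append(
            ScoreSet(str(r.sample_id), z, tr, f, ratio, float(r.total_unique))
        )
    return out
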