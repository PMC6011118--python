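"""End-to-end driver: count → gate → score → calibrate → classify → evaluate.

Two input modes share the downstream stages:

* ``synthetic`` — simulate a labelled cohort plus a euploid reference panel
  (the default panel size is 2, matching the original protocol's two euploid
  reference pregnancies) and run the full analysis with known truth.
* ``counts`` — read per-sample count tables (and optional fragment-length
  files) listed in a manifest TSV, with a pre-built panel/cut-offs or truth
  labels to calibrate from.

Calibration defaults to resubstitution — cut-offs fitted and evaluated on
the same cohort, as the original study did; ``holdout_fraction > 0``
switches to the statistically sounder held-out split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .alignments import ChromosomeCounts, informative, MIN_INFORMATIVE_READS
from .classify import (
    CutoffSet,
    SampleCall,
    STATUS_EUPLOID,
    TRISOMY_STATUS,
    calibrate,
    classify,
)
from .evaluate import ConfusionSummary, evaluate
from .fetal_fraction import (
    LONG_WINDOW,
    NonEvaluableSample,
    SHORT_WINDOW,
    SIZE_RATIO_GATE,
    size_ratio,
)
from .genome import GenomeTable
from .scores import ReferencePanel, ScoreSet, build_reference, score_sample, scores_to_frame
from .synthetic import SimulationConfig, simulate_cohort, simulate_counts


@dataclass
class PipelineConfig:
    mode: str = "synthetic"
    # synthetic-mode cohort
    n_euploid: int = 159
    n_t21: int = 34
    n_t18: int = 18
    n_t13: int = 6
    ff_range: tuple[float, float] = (0.04, 0.20)
    depth_range: tuple[int, int] = (1_200_000, 9_000_000)
    seed: int = 0
    bin_width: int | None = 1_000_000
    n_fragments: int = 20_000
    gc_bias_slope: float = 0.3
    n_reference: int = 2
    # counts mode
    manifest: str | None = None
    genome_table: str | None = None
    panel_json: str | None = None
    cutoffs_json: str | None = None
    # shared analysis settings
    gc_model: str = "strata"
    min_reads: int = MIN_INFORMATIVE_READS
    short_window: tuple[float, float] = SHORT_WINDOW
    long_window: tuple[float, float] = LONG_WINDOW
    size_gate: float = SIZE_RATIO_GATE
    rule: str | None = None  # None: let calibration select the rule
    holdout_fraction: float = 0.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        for name in ("ff_range", "depth_range", "short_window", "long_window"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


@dataclass
class GatedSample:
    counts: ChromosomeCounts
    size_ratio: float | None  # None: no fragments in the long window
    informative: bool
    passes_size_gate: bool | None


@dataclass
class PipelineResult:
    calls: list[SampleCall]
    summary: ConfusionSummary | None
    cutoffs: CutoffSet
    panel: ReferencePanel
    scores: pd.DataFrame
    truth: dict[str, str] | None
    log: list[str]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = [
            {"sample_id": c.sample_id, "status": c.status, "positives": ",".join(c.positives)}
            for c in self.calls
        ]
        pd.DataFrame(rows).to_csv(outdir / "calls.tsv", sep="\t", index=False)
        self.scores.to_csv(outdir / "scores.tsv", sep="\t", index=False)
        self.cutoffs.to_json(outdir / "cutoffs.json")
        self.panel.to_json(outdir / "panel.json")
        if self.summary is not None:
            (outdir / "summary.json").write_text(
                json.dumps(self.summary.to_dict(), indent=2)
            )
        (outdir / "run.log").write_text("\n".join(self.log) + "\n")


def _gate_sample(
    counts: ChromosomeCounts,
    lengths: Sequence[int] | None,
    config: PipelineConfig,
) -> GatedSample:
    is_informative = informative(counts, config.min_reads)
    if lengths is None:
        # no fragment-length data: the size gate cannot veto the sample
        return GatedSample(counts, None, is_informative, True)
    try:
        res = size_ratio(
            lengths, config.short_window, config.long_window, config.size_gate
        )
    except NonEvaluableSample:
        return GatedSample(counts, None, is_informative, None)
    return GatedSample(counts, res.size_ratio, is_informative, res.passes_gate)


def _score_cohort(
    gated: list[GatedSample],
    panel: ReferencePanel,
    genome: GenomeTable,
    config: PipelineConfig,
) -> dict[str, ScoreSet]:
    out = {}
    for g in gated:
        if not g.informative or g.passes_size_gate is not True:
            continue
        out[g.counts.sample_id] = score_sample(
            g.counts, panel, genome, size_ratio=g.size_ratio, gc_model=config.gc_model
        )
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    log: list[str] = []
    genome = (
        GenomeTable.from_tsv(config.genome_table)
        if config.genome_table
        else GenomeTable.hg19()
    )

    truth: dict[str, str] | None
    if config.mode == "synthetic":
        cohort = simulate_cohort(
            config.n_euploid,
            config.n_t21,
            config.n_t18,
            config.n_t13,
            ff_range=config.ff_range,
            depth_range=config.depth_range,
            seed=config.seed,
            genome=genome,
            bin_width=config.bin_width,
            n_fragments=config.n_fragments,
            gc_bias_slope=config.gc_bias_slope,
        )
        truth = {
            s.sample_id: TRISOMY_STATUS.get(s.truth.trisomy, STATUS_EUPLOID)
            for s in cohort
        }
        gated = [_gate_sample(s.counts, s.lengths, config) for s in cohort]
        ref_rng = np.random.default_rng([3, config.seed])
        ref_counts = []
        for i in range(config.n_reference):
            rc, _ = simulate_counts(
                SimulationConfig(
                    seed=int(ref_rng.integers(2**31)),
                    n_reads=int(np.mean(config.depth_range)),
                    trisomy="none",
                    fetal_fraction=float(np.mean(config.ff_range)),
                    gc_bias_slope=config.gc_bias_slope,
                ),
                genome,
                bin_width=config.bin_width,
                sample_id=f"ref{i + 1:02d}",
            )
            ref_counts.append(rc)
        panel = build_reference(ref_counts, genome, gc_model=config.gc_model)
        log.append(
            f"simulated cohort: {len(cohort)} samples "
            f"({config.n_euploid} euploid, {config.n_t21} T21, "
            f"{config.n_t18} T18, {config.n_t13} T13), seed {config.seed}"
        )
    elif config.mode == "counts":
        if config.manifest is None:
            raise ValueError("counts mode requires a manifest TSV")
        manifest = pd.read_csv(config.manifest, sep="\t")
        base = Path(config.manifest).parent
        gated = []
        truth = {} if "truth_label" in manifest.columns else None
        for row in manifest.itertuples():
            counts = ChromosomeCounts.from_tsv(
                base / str(row.counts_path), sample_id=str(row.sample_id)
            )
            lengths = None
            if getattr(row, "lengths_path", None) and pd.notna(row.lengths_path):
                lengths = np.loadtxt(base / str(row.lengths_path), dtype=int, ndmin=1)
            gated.append(_gate_sample(counts, lengths, config))
            if truth is not None:
                truth[str(row.sample_id)] = str(row.truth_label)
        if config.panel_json is None:
            raise ValueError("counts mode requires a pre-built panel JSON")
        panel = ReferencePanel.from_json(config.panel_json)
        log.append(f"loaded {len(gated)} samples from {config.manifest}")
    else:
        raise ValueError(f"unknown pipeline mode {config.mode!r}")

    scored = _score_cohort(gated, panel, genome, config)
    n_gated_out = len(gated) - len(scored)
    log.append(
        f"scored {len(scored)} informative samples; "
        f"{n_gated_out} excluded by read-count/size gates"
    )

    # --- cut-offs ----------------------------------------------------------
    if config.cutoffs_json:
        cutoffs = CutoffSet.from_json(config.cutoffs_json)
        eval_ids = list(scored)
    elif truth is not None:
        ids = sorted(scored)
        if config.holdout_fraction > 0:
            rng = np.random.default_rng([4, config.seed])
            ids = [ids[i] for i in rng.permutation(len(ids))]
            n_cal = int(round((1 - config.holdout_fraction) * len(ids)))
            cal_ids, eval_ids = ids[:n_cal], ids[n_cal:]
        else:
            cal_ids, eval_ids = ids, ids
        cutoffs = calibrate([scored[i] for i in cal_ids], {i: truth[i] for i in cal_ids})
        if config.rule:
            cutoffs = CutoffSet(cutoffs.cutoffs, config.rule, cutoffs.provenance)
        log.append(
            f"calibrated on {len(cal_ids)} samples; selected rule {cutoffs.rule}"
        )
    else:
        raise ValueError("need either cutoffs_json or truth labels to calibrate")

    # --- classify ----------------------------------------------------------
    calls = []
    scored_eval = set(eval_ids)
    for g in gated:
        sid = g.counts.sample_id
        if sid in scored:
            if sid not in scored_eval:
                continue  # used for calibration only (held-out protocol)
            calls.append(
                classify(
                    scored[sid],
                    cutoffs,
                    informative=g.informative,
                    size_gate=g.passes_size_gate,
                )
            )
        else:
            placeholder = ScoreSet(sid, {}, {}, {}, g.size_ratio, g.counts.total_unique)
            status_gate = g.passes_size_gate
            calls.append(
                classify(placeholder, cutoffs, informative=g.informative, size_gate=status_gate)
            )

    summary = None
    if truth is not None:
        eval_truth = {c.sample_id: truth[c.sample_id] for c in calls}
        summary = evaluate(calls, eval_truth)
        log.append(
            f"overall sensitivity {summary.overall_sensitivity_pct}%, "
            f"specificity {summary.overall_specificity_pct}% "
            f"({summary.n_excluded} excluded)"
        )
    frame = scores_to_frame([scored[i] for i in sorted(scored)])
    return PipelineResult(calls, summary, cutoffs, panel, frame, truth, log)
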