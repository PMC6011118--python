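# Methods

## The screening problem

Maternal plasma carries cell-free DNA (cfDNA) from both mother and placenta;
the placental ("fetal") compartment is typically 4–20% of the total. If the
fetus carries a trisomy, reads from the affected chromosome are slightly
overrepresented among uniquely mapped shallow-WGS reads: with fetal fraction
*ff*, the affected chromosome's read share is multiplied by `1 + ff/2`
(the fetal compartment contributes three copies instead of two). At *ff* =
0.10 this is a 5% excess on a chromosome share of ~1.3–1.6% — detectable
only against tight count statistics, which is why the pipeline's substance
is careful counting, bias correction and calibration rather than any single
large effect.

## Pipeline model

For each sample, uniquely mapped reads (primary, mapped, MAPQ ≥ 1 by
default) are counted over chr1..22 + chrX; chrY is excluded throughout
(maternal plasma is overwhelmingly female-derived and the targets are
autosomal). A chromosome's **percent genomic representation** is
`%GR(c) = 100 · N_c / Σ N`, so %GR sums to exactly 100 over the included
set. Three statistics compare a sample against a euploid reference panel
(per-chromosome mean and SD of %GR, SD with the n−1 denominator):

* **Z** = (%GR − mean_ref) / SD_ref, on *raw* (uncorrected) %GR — this is
  the classical chromosome-representation z-statistic and deliberately
  ignores GC content;
* **TR (Trisomy Ratio)** = GC-corrected %GR / GC-corrected panel mean.
  Euploid expectation 1; trisomy expectation `(1 + ff/2)/(1 + ff·w_c/2)`
  ≈ `1 + ff/2` (the denominator is the fixed-total renormalization, a
  ~0.2% effect for chr21), so `2·(TR − 1)` is a dosage-based estimate of
  the fetal fraction;
* **FGR (Fractional Genomic Representation)** = the GC-corrected %GR
  itself, judged against its own calibrated cut-off rather than as a ratio.

**GC correction.** Read density depends on local GC content. Counts are
tallied into fixed-width bins; each bin's count-per-bp is compared with the
fitted density-vs-GC trend and rescaled by `mean rate / fitted rate(gc)`.
The default trend fit is stratum re-weighting over 0.5%-wide GC strata —
parameter-light and exactly the identity when all bins share one GC value;
LOESS (statsmodels lowess, frac 0.3) and a global linear fit are selectable
alternatives. Strata without signal borrow the nearest stratum with signal;
nonpositive fitted rates (possible for the unconstrained fits) fall back to
the global mean rate, i.e. no correction for those bins. Correction requires
at least 20 bins with nonzero counts. The genome-wide default bin width is
50 kb; analyses and tests in this repository use 1 Mb bins (~3,030 bins
genome-wide), which keeps simulation cheap while leaving dozens of bins per
GC stratum.

**Gates.** A sample is *informative* only with strictly more than 1,000,000
unique reads (the threshold is configurable; some published protocols use
3.5 M). Fetal-fraction adequacy is gated by the fragment-size ratio
`n_short/n_long` with short = [100, 150] bp and long = [163, 169] bp
(endpoint-inclusive; windows configurable): fetal cfDNA is shorter, so the
ratio rises with fetal fraction. The gate is strict: a ratio of exactly
0.84 fails. A sample with an empty long window is *non-evaluable* — a
distinct state from a gate failure. An optional ordinary-least-squares
calibration maps ratio to a fetal-fraction estimate (clamped to [0, 1]);
only the gate, not the estimate, feeds classification.

**Calibration and classification.** Per target chromosome (13, 18, 21) and
per score, a cut-off is chosen by sweeping all midpoints between adjacent
sorted unique score values plus ±∞ and maximizing Youden's J = sensitivity +
specificity − 1 (ties break toward higher specificity, then the higher
cut-off; a sample is positive when the score is strictly greater than the
cut-off). ROC cases are the samples with that trisomy and controls are the
euploid samples. Candidate combination rules (each single score, each pair
as a conjunction, any-two, all-three) are then compared by total
misclassifications on the calibration cohort; ties resolve to the TR∧FGR
conjunction, which is also the selected rule in practice. When several
chromosomes fire, the call is the chromosome with the largest TR, with the
full positive set retained for audit. Calibration defaults to
resubstitution (cut-offs fitted and evaluated on the same cohort, matching
the original protocol); a held-out split (`holdout_fraction`) is available
and is the statistically sounder choice when enough samples exist.

**Evaluation.** Errors are three-way: *false positive* (euploid called
trisomic), *false negative* (trisomic called euploid), *incorrectly
identified* (trisomic called the wrong trisomy). Overall sensitivity counts
incorrectly identified samples as detected (an abnormality was flagged);
per-chromosome sensitivity does not, and an incorrectly identified sample
is simultaneously a per-chromosome FN for its true chromosome and FP for
the called one. Per-chromosome specificity uses all samples whose truth is
not that trisomy (euploid + other trisomies) as the denominator — the only
convention consistent with the published per-trisomy values this evaluator
reproduces. Noninformative/non-evaluable samples are excluded and counted.
Percentages are rounded half-up to two decimals.

## Synthetic data: what it emulates and what it does not

No cohort data are deposited, so all quantitative behaviour is established
on a seeded generator:

* counts are multinomial over hg19 length-proportional chromosome weights,
  modulated by a linear GC bias `1 + slope·(GC − mean GC)` (default slope
  0.3, chromosome- or bin-level) and the `1 + ff/2` trisomy dosage;
* fragment lengths are a maternal/fetal normal mixture — maternal 166 ± 20
  bp, fetal 143 ± 20 bp, truncated to [50, 400] bp and rounded to whole bp —
  consistent with observed cfDNA size distributions and a typical read
  length around 145 nt;
* cohorts draw per-sample fetal fraction uniformly from 4–20% (the typical
  screening range) and unique depth from 1.2–9 M reads; per-bin GC values
  are synthesized around each chromosome's global GC (SD 0.04) because no
  sequence ships with the repository.

The generator does **not** model PCR duplicates, mappability holes,
sequence-specific error, GC bias nonlinearity, maternal CNVs, or confined
placental mosaicism — the dominant biological source of real false
positives. Passing tests therefore demonstrate the *statistical machinery*
(counting, correction, calibration, bookkeeping) under the model's
assumptions, not clinical performance; the published cohort metrics are
reproduced only as evaluation-semantics worked examples from the arms'
enumerated outcome tables.

## Numerical and design choices

* Multinomial totals are conserved exactly; all randomness flows from a
  single config seed through separate substreams for counts, fragments and
  SAM layout, so outputs are byte-identical across runs.
* The two-sample reference panel of the original protocol is reproducible
  but fragile (`build_reference` warns below 10 samples); with a 2-sample
  panel the SD estimate is |x₁−x₂|/√2 and Z cut-offs become erratic, which
  the rule-selection step absorbs by preferring TR∧FGR. A degenerate SD of
  0 raises rather than returning ±∞.
* Problem sizes for the repository's own experiments: trisomy-ratio
  recovery uses 100 replicates at 10 M reads; Z null calibration uses 200
  replicates, each against a fresh 50-sample panel at 5 M reads (pooling
  the three targets, so the mean estimate has SD ≈ 0.04 z units — a fresh
  panel per replicate prevents one panel's sampling error from dominating);
  end-to-end recovery uses ten 200-sample cohorts at fetal fraction ≥ 0.10
  and depth ≥ 5 M.
* Whether the published analysis included chrX in denominators, used
  per-flow-cell reference ranges, or defined the ratio over counts versus
  proportions is not recoverable; all are configuration here (chrX
  included, global panel, counts ratio).

## Known limitations

Uniqueness is a MAPQ surrogate, not a mapper-specific multiread audit; the
GC model is linear where real bias is smooth but nonlinear; fragment-length
truncation shifts component means by < 0.5 bp at defaults and is ignored;
the size-ratio windows are conventions, and simulated ratios (≈1.7–2.5)
sit well above the 0.84 gate, so gate failures must be constructed rather
than expected from the generator's defaults.
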