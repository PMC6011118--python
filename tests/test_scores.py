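"""%GR arithmetic, GC correction, reference panels, and the Z/TR/FGR scores."""

import numpy as np
import pandas as pd
import pytest

from nipt.alignments import ChromosomeCounts
from nipt.scores import (
    DegenerateReference,
    build_reference,
    fgr,
    gc_correct,
    percent_representation,
    score_sample,
    trisomy_ratio,
    z_score,
)
from nipt.synthetic import SimulationConfig, simulate_counts


def _counts(mapping, sample_id="s", bin_counts=None):
    return ChromosomeCounts(sample_id, dict(mapping), bin_counts)


class TestPercentRepresentation:
    def test_direct_arithmetic(self):
        counts = _counts({"chr21": 13, "chr1": 987})
        assert percent_representation(counts, "chr21") == pytest.approx(1.3)

    def test_absent_chromosome_rejected(self):
        with pytest.raises(KeyError):
            percent_representation(_counts({"chr1": 10}), "chr21")

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            percent_representation(_counts({"chr1": 0}), "chr1")

    def test_shares_sum_to_100(self, genome):
        counts, _ = simulate_counts(SimulationConfig(seed=8, n_reads=500_000), genome)
        assert sum(counts.percent(c) for c in counts.counts) == pytest.approx(100.0)

    def test_euploid_share_matches_base_weight(self, genome):
        n = 2_000_000
        counts, _ = simulate_counts(
            SimulationConfig(seed=9, n_reads=n, fetal_fraction=0.0, gc_bias_slope=0.0),
            genome,
        )
        w = genome.weights()["chr21"]
        sd_pct = 100 * np.sqrt(w * (1 - w) / n)
        assert abs(counts.percent("chr21") - 100 * w) < 5 * sd_pct


class TestGCCorrect:
    def test_uniform_gc_is_identity(self):
        bins = pd.DataFrame(
            {
                "chrom": ["chr1"] * 30,
                "start": np.arange(30) * 1000,
                "end": (np.arange(30) + 1) * 1000,
                "gc": 0.41,
                "count": np.arange(1, 31),
            }
        )
        counts = _counts({"chr1": bins["count"].sum()}, bin_counts=bins)
        corrected = gc_correct(counts)
        assert corrected.counts["chr1"] == pytest.approx(counts.counts["chr1"])
        assert np.allclose(corrected.bin_counts["count"], bins["count"])

    def test_no_bias_simulation_nearly_unchanged(self, genome):
        counts, _ = simulate_counts(
            SimulationConfig(seed=10, n_reads=3_000_000, gc_bias_slope=0.0),
            genome,
            bin_width=1_000_000,
        )
        corrected = gc_correct(counts, genome)
        for chrom in counts.counts:
            raw, corr = counts.percent(chrom), corrected.percent(chrom)
            assert abs(corr - raw) / raw < 0.01, chrom

    def test_correction_moves_gc_extreme_chromosome_toward_weight(self, genome):
        """Averaged over replicates, corrected %GR of the most GC-extreme
        chromosome (chr19) is closer to its base weight than raw %GR."""
        raw_err, corr_err = [], []
        target = "chr19"
        expected = 100 * genome.weights()[target]
        for i in range(50):
            counts, _ = simulate_counts(
                SimulationConfig(seed=400 + i, n_reads=1_000_000, gc_bias_slope=0.5),
                genome,
                bin_width=2_000_000,
            )
            corrected = gc_correct(counts, genome)
            raw_err.append(counts.percent(target) - expected)
            corr_err.append(corrected.percent(target) - expected)
        assert abs(np.mean(corr_err)) < abs(np.mean(raw_err))

    def test_correction_reduces_replicate_variance_under_bias(self, genome):
        raw_vals, corr_vals = [], []
        for i in range(50):
            counts, _ = simulate_counts(
                SimulationConfig(seed=700 + i, n_reads=1_000_000, gc_bias_slope=0.5),
                genome,
                bin_width=2_000_000,
            )
            raw_vals.append(counts.percent("chr19"))
            corr_vals.append(gc_correct(counts, genome).percent("chr19"))
        assert np.var(corr_vals) < np.var(raw_vals)

    @pytest.mark.parametrize("model", ["loess", "linear"])
    def test_alternative_models_also_debias(self, genome, model):
        counts, _ = simulate_counts(
            SimulationConfig(seed=55, n_reads=2_000_000, gc_bias_slope=0.5),
            genome,
            bin_width=2_000_000,
        )
        corrected = gc_correct(counts, genome, model=model)
        expected = 100 * genome.weights()["chr19"]
        assert abs(corrected.percent("chr19") - expected) < abs(
            counts.percent("chr19") - expected
        )

    def test_requires_bins_and_enough_signal(self):
        with pytest.raises(ValueError, match="bin-level"):
            gc_correct(_counts({"chr1": 10}))
        bins = pd.DataFrame(
            {
                "chrom": ["chr1"] * 5,
                "start": np.arange(5) * 1000,
                "end": (np.arange(5) + 1) * 1000,
                "gc": 0.4,
                "count": 1,
            }
        )
        with pytest.raises(ValueError, match="bins"):
            gc_correct(_counts({"chr1": 5}, bin_counts=bins))


class TestReferencePanel:
    def test_two_point_mean_and_sd(self):
        a = _counts({"chr21": 12, "chr1": 988}, "a")  # %GR21 = 1.2
        b = _counts({"chr21": 14, "chr1": 986}, "b")  # %GR21 = 1.4
        with pytest.warns(UserWarning, match="fragile"):
            panel = build_reference([a, b], gc_model="none")
        assert panel.raw_mean["chr21"] == pytest.approx(1.3)
        assert panel.raw_sd["chr21"] == pytest.approx(0.2 / np.sqrt(2))

    def test_identical_samples_degenerate_sd(self):
        a = _counts({"chr21": 13, "chr1": 987}, "a")
        b = _counts({"chr21": 13, "chr1": 987}, "b")
        panel = build_reference([a, b], gc_model="none")
        assert panel.raw_sd["chr21"] == 0.0
        with pytest.raises(DegenerateReference):
            z_score(1.3, panel, "chr21")

    def test_panel_mean_matches_generator_expectation(self, genome):
        samples = [
            simulate_counts(
                SimulationConfig(seed=900 + i, n_reads=1_000_000, gc_bias_slope=0.0),
                genome,
            )[0]
            for i in range(50)
        ]
        panel = build_reference(samples, genome, gc_model="none")
        w = genome.weights()["chr21"]
        se = 100 * np.sqrt(w * (1 - w) / 1_000_000) / np.sqrt(50)
        assert abs(panel.raw_mean["chr21"] - 100 * w) < 3 * se

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_reference([_counts({"chr1": 1})])


class TestScores:
    def test_z_identity_and_arithmetic(self):
        panel = _make_panel(1.30, 0.01)
        assert z_score(1.30, panel, "chr21") == pytest.approx(0.0)
        assert z_score(1.33, panel, "chr21") == pytest.approx(3.0)

    def test_z_affine_invariance(self):
        panel = _make_panel(1.30, 0.01)
        shifted = _make_panel(1.30 + 5, 0.01)
        assert z_score(1.33, panel, "chr21") == pytest.approx(
            z_score(1.33 + 5, shifted, "chr21")
        )

    def test_tr_identity_and_degenerate(self):
        panel = _make_panel(1.30, 0.01)
        assert trisomy_ratio(1.30, panel, "chr21") == pytest.approx(1.0)
        with pytest.raises(DegenerateReference):
            trisomy_ratio(1.3, _make_panel(0.0, 0.01), "chr21")

    def test_fgr_is_corrected_percent(self):
        counts = _counts({"chr21": 13, "chr1": 987})
        assert fgr(counts, "chr21") == pytest.approx(1.3)

    def test_sample_at_panel_mean_scores_neutrally(self, genome):
        samples = [
            simulate_counts(
                SimulationConfig(seed=50 + i, n_reads=1_000_000, gc_bias_slope=0.0),
                genome,
            )[0]
            for i in range(10)
        ]
        panel = build_reference(samples, genome, gc_model="none")
        mean_gr = panel.raw_mean["chr21"]
        assert z_score(mean_gr, panel, "chr21") == pytest.approx(0.0)
        assert trisomy_ratio(panel.corrected_mean["chr21"], panel, "chr21") == pytest.approx(1.0)

    def test_t18_scores_highest_on_its_own_chromosome(self, genome):
        samples = [
            simulate_counts(
                SimulationConfig(seed=60 + i, n_reads=2_000_000), genome,
                bin_width=2_000_000,
            )[0]
            for i in range(10)
        ]
        panel = build_reference(samples, genome)
        wins = 0
        reps = 20
        for i in range(reps):
            counts, _ = simulate_counts(
                SimulationConfig(
                    seed=3000 + i, n_reads=2_000_000,
                    trisomy="chr18", fetal_fraction=0.15,
                ),
                genome,
                bin_width=2_000_000,
            )
            ss = score_sample(counts, panel, genome)
            wins += ss.z["chr18"] > max(ss.z["chr13"], ss.z["chr21"])
        assert wins >= int(0.95 * reps)

    def test_score_sample_deterministic(self, genome):
        samples = [
            simulate_counts(SimulationConfig(seed=80 + i, n_reads=500_000), genome,
                            bin_width=2_000_000)[0]
            for i in range(5)
        ]
        panel = build_reference(samples, genome)
        counts, _ = simulate_counts(
            SimulationConfig(seed=99, n_reads=500_000), genome, bin_width=2_000_000
        )
        a = score_sample(counts, panel, genome)
        b = score_sample(counts, panel, genome)
        assert a == b


def _make_panel(mean, sd):
    from nipt.scores import ReferencePanel

    chroms = ("chr13", "chr18", "chr21")
    return ReferencePanel(
        chromosomes=chroms,
        raw_mean={c: mean for c in chroms},
        raw_sd={c: sd for c in chroms},
        corrected_mean={c: mean for c in chroms},
        corrected_sd={c: sd for c in chroms},
        n_reference=2,
        gc_model="none",
    )
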