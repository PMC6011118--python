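"""ROC cut-off sweep (vs brute-force oracle), rule calibration, classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nipt.classify import (
    RULES,
    CutoffSet,
    calibrate,
    classify,
    roc_cutoff,
)
from nipt.scores import ScoreSet

TARGETS = ("chr13", "chr18", "chr21")


def brute_force_best_j(scores, labels):
    """Independent oracle: exhaustive threshold enumeration with numpy."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    u = np.unique(s)
    candidates = np.concatenate(([-np.inf], (u[:-1] + u[1:]) / 2, [np.inf], u))
    sens = (s[y][:, None] > candidates).mean(axis=0)
    spec = (s[~y][:, None] <= candidates).mean(axis=0)
    return float((sens + spec - 1).max())


def _scoreset(sid, z=0.0, tr=1.0, fgr_val=1.3, per_chrom=None):
    per_chrom = per_chrom or {}
    zd, td, fd = {}, {}, {}
    for c in TARGETS:
        cz, ct, cf = per_chrom.get(c, (z, tr, fgr_val))
        zd[c], td[c], fd[c] = cz, ct, cf
    return ScoreSet(sid, zd, td, fd, size_ratio=1.2, total_unique=5_000_000)


def _cutoffs(rule="TR_AND_FGR", z=3.0, tr=1.05, fgr_val=1.4):
    return CutoffSet({c: {"z": z, "tr": tr, "fgr": fgr_val} for c in TARGETS}, rule)


class TestRocCutoff:
    def test_perfectly_separated_classes(self):
        res = roc_cutoff([0.1, 0.2, 0.9, 1.1], [False, False, True, True])
        assert res.youden_j == pytest.approx(1.0)
        assert 0.2 < res.cutoff < 0.9

    def test_midpoint_rule_worked_example(self):
        res = roc_cutoff([1, 2, 3, 4], [False, False, True, True])
        assert res.cutoff == pytest.approx(2.5)
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_cutoff([1.0, 2.0], [True, True])

    def test_sweep_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = int(rng.integers(4, 120))
            scores = rng.normal(size=n).round(2)  # rounding forces ties
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            res = roc_cutoff(scores, labels)
            assert res.youden_j == pytest.approx(brute_force_best_j(scores, labels))

    @given(st.data())
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_sweep_matches_brute_force_property(self, data):
        n = data.draw(st.integers(4, 60))
        scores = data.draw(
            st.lists(st.integers(-5, 5), min_size=n, max_size=n).map(
                lambda xs: [x / 2 for x in xs]
            )
        )
        labels = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        if all(labels) or not any(labels):
            return
        res = roc_cutoff(scores, labels)
        assert res.youden_j == pytest.approx(brute_force_best_j(scores, labels))

    def test_tie_breaks_prefer_specificity_then_higher_cutoff(self):
        # cases [2, 3], controls [1, 4]: several cutoffs share the best J
        res = roc_cutoff([1, 2, 3, 4], [False, True, True, False])
        alt = brute_force_best_j([1, 2, 3, 4], [False, True, True, False])
        assert res.youden_j == pytest.approx(alt)
        # among J-ties the sweep must report the most specific, highest cutoff
        assert res.specificity >= 0.5


class TestClassify:
    def test_all_below_cutoffs_is_euploid(self):
        call = classify(_scoreset("a"), _cutoffs())
        assert call.status == "euploid"
        assert call.positives == ()

    def test_tr_and_fgr_conjunction_calls_trisomy21(self):
        ss = _scoreset("b", per_chrom={"chr21": (1.0, 1.10, 1.55)})
        call = classify(ss, _cutoffs())
        assert call.status == "trisomy21"
        assert call.positives == ("chr21",)

    def test_unsatisfied_conjunction_stays_euploid(self):
        ss = _scoreset("c", per_chrom={"chr18": (1.0, 1.10, 1.30)})  # fgr below
        call = classify(ss, _cutoffs())
        assert call.status == "euploid"

    def test_gates_override_scores(self):
        ss = _scoreset("d", per_chrom={"chr21": (9.0, 1.5, 2.0)})
        assert classify(ss, _cutoffs(), informative=False).status == "noninformative"
        assert classify(ss, _cutoffs(), size_gate=False).status == "noninformative"
        assert classify(ss, _cutoffs(), size_gate=None).status == "non_evaluable"

    def test_multi_positive_arbitration_by_largest_tr(self):
        ss = _scoreset(
            "e",
            per_chrom={"chr21": (5.0, 1.08, 1.6), "chr18": (5.0, 1.12, 1.6)},
        )
        call = classify(ss, _cutoffs())
        assert call.status == "trisomy18"
        assert set(call.positives) == {"chr18", "chr21"}

    def test_raising_cutoffs_never_creates_positives(self):
        rng = np.random.default_rng(5)
        base = _cutoffs()
        for i in range(50):
            per = {
                c: tuple(rng.normal([1.0, 1.05, 1.4], [2.0, 0.05, 0.1]))
                for c in TARGETS
            }
            ss = _scoreset(f"m{i}", per_chrom=per)
            before = set(classify(ss, base).positives)
            raised = CutoffSet(
                {c: {k: v + abs(rng.normal()) for k, v in base.cutoffs[c].items()}
                 for c in TARGETS},
                base.rule,
            )
            after = set(classify(ss, raised).positives)
            assert after <= before

    def test_missing_target_cutoff_raises(self):
        cs = CutoffSet({"chr21": {"z": 3, "tr": 1.05, "fgr": 1.4}}, "TR_AND_FGR")
        with pytest.raises(KeyError, match="chr13"):
            classify(_scoreset("f"), cs)


class TestCalibrate:
    def _cohort(self, seed=0, n_eup=60, n_tri=8, noise_score=None):
        """Synthetic score table: TR/FGR informative, Z optionally pure noise."""
        rng = np.random.default_rng(seed)
        sets, truth = [], {}
        i = 0
        for status, chrom, n in [
            ("euploid", None, n_eup),
            ("trisomy21", "chr21", n_tri),
            ("trisomy18", "chr18", n_tri),
            ("trisomy13", "chr13", n_tri),
        ]:
            for _ in range(n):
                i += 1
                sid = f"c{i:03d}"
                per = {}
                for c in TARGETS:
                    bump = 0.10 if c == chrom else 0.0
                    z = rng.normal(0, 1) + (4.0 * (c == chrom) if noise_score != "z" else 0.0)
                    tr = rng.normal(1 + bump, 0.01)
                    fg = rng.normal((1 + bump) * 1.3, 0.013)
                    per[c] = (z, tr, fg)
                sets.append(_scoreset(sid, per_chrom=per))
                truth[sid] = status
        return sets, truth

    def test_selects_default_rule_and_separates(self):
        sets, truth = self._cohort(seed=1)
        cs = calibrate(sets, truth)
        assert cs.rule == "TR_AND_FGR"
        assert cs.provenance["rule_errors"]["TR_AND_FGR"] <= min(
            cs.provenance["rule_errors"][r] for r in ("Z", "TR", "FGR")
        )

    def test_noise_score_rules_never_beat_tr_alone(self):
        sets, truth = self._cohort(seed=2, noise_score="z")
        cs = calibrate(sets, truth)
        errs = cs.provenance["rule_errors"]
        assert errs["Z"] >= errs["TR"]
        assert errs["Z_AND_TR"] >= errs["TR"] or errs["Z_AND_FGR"] >= errs["TR"]

    def test_deterministic(self):
        sets, truth = self._cohort(seed=3)
        assert calibrate(sets, truth) == calibrate(sets, truth)

    def test_missing_class_rejected(self):
        sets, truth = self._cohort(seed=4, n_tri=0)
        with pytest.raises(ValueError, match="calibration needs"):
            calibrate(sets, truth)
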