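import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import t1std as t


class TestSummarise:
    def test_constant_values_have_degenerate_ci(self):
        s = t.summarise([1000.0, 1000.0, 1000.0])
        assert s.sd == 0 and s.ci_low == s.ci_high == 1000.0

    def test_textbook_t_interval(self):
        # oracle: 1100 +- t(0.975, df=2) * 100 / sqrt(3)
        s = t.summarise([1000.0, 1100.0, 1200.0])
        half = stats.t.ppf(0.975, 2) * 100 / np.sqrt(3)
        assert s.mean == 1100.0
        assert s.ci_low == pytest.approx(1100.0 - half, abs=1e-9)
        assert s.ci_high == pytest.approx(1100.0 + half, abs=1e-9)
        assert s.cov == pytest.approx(100 / 1100, abs=1e-12)

    def test_single_value_rejected(self):
        with pytest.raises(t.ConfigurationError):
            t.summarise([1000.0])


class TestCompareCohorts:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        g = rng.normal(1100, 50, 30)
        comp = t.compare_cohorts({"a": g, "b": g.copy()})
        assert not any(comp.significant.values())

    def test_well_separated_groups_significant(self):
        rng = np.random.default_rng(1)
        comp = t.compare_cohorts({
            "healthy": rng.normal(1100, 50, 50),
            "amy": rng.normal(1400, 50, 50),
        })
        assert comp.significant[("healthy", "amy")]
        assert comp.omnibus_p <= 0.05

    def test_constant_group_routes_nonparametric(self):
        with pytest.warns(UserWarning, match="constant"):
            comp = t.compare_cohorts({
                "a": [1100.0] * 5,
                "b": [1000.0, 1010.0, 1020.0, 1030.0],
            })
        assert comp.route == "nonparametric"

    def test_nonnormal_groups_route_nonparametric(self):
        rng = np.random.default_rng(2)
        comp = t.compare_cohorts({
            "a": rng.exponential(50, 60) + 1000,
            "b": rng.exponential(50, 60) + 1000,
        })
        assert comp.route == "nonparametric"

    def test_type_i_error_near_alpha_under_null(self):
        """Pairwise false-positive rate ~ alpha for same-distribution
        groups (reduced replicates; binomial tolerance)."""
        rng = np.random.default_rng(3)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            comp = t.compare_cohorts({
                "a": rng.normal(1100, 60, 20),
                "b": rng.normal(1100, 60, 20),
            })
            hits += comp.significant[("a", "b")]
        rate = hits / n_rep
        assert 0.005 <= rate <= 0.105


class TestRocAnalysis:
    def test_perfect_separation(self):
        roc = t.roc_analysis([1000, 1010], [1300, 1310])
        assert roc.sensitivity == 100.0 and roc.specificity == 100.0
        assert roc.evidence and roc.auc == 1.0

    def test_overlapping_samples_auc_by_pair_counting(self):
        # oracle: exhaustive pair count 14/16 (ties half)
        roc = t.roc_analysis([1, 2, 3, 4], [3, 4, 5, 6])
        assert roc.auc == pytest.approx(14 / 16, abs=1e-12)

    def test_tied_youden_takes_lowest_threshold(self):
        # brute force over candidates: J = 50% at 2.5, 3.5, 4.5
        roc = t.roc_analysis([1, 2, 3, 4], [3, 4, 5, 6])
        assert roc.threshold == 2.5
        assert roc.sensitivity + roc.specificity == pytest.approx(150.0)

    def test_auc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(7)
        neg = rng.normal(1100, 60, 40)
        pos = rng.normal(1200, 80, 30)
        roc = t.roc_analysis(neg, pos)
        expected = roc_auc_score(
            np.r_[np.zeros(40), np.ones(30)], np.r_[neg, pos])
        assert roc.auc == pytest.approx(expected, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(t.ConfigurationError):
            t.roc_analysis([], [1.0])

    @given(st.floats(min_value=0.1, max_value=5),
           st.floats(min_value=-100, max_value=100))
    def test_invariant_under_increasing_affine_transform(self, a, b):
        neg = np.array([1000.0, 1050.0, 1100.0, 1150.0])
        pos = np.array([1120.0, 1200.0, 1260.0])
        r1 = t.roc_analysis(neg, pos)
        r2 = t.roc_analysis(a * neg + b, a * pos + b)
        assert r2.auc == pytest.approx(r1.auc, abs=1e-12)
        assert r2.sensitivity == r1.sensitivity
        assert r2.specificity == r1.specificity

    def test_label_swap_complements_auc(self):
        rng = np.random.default_rng(8)
        neg = rng.normal(1100, 60, 25)
        pos = rng.normal(1250, 60, 25)
        assert t.roc_analysis(neg, pos).auc == pytest.approx(
            1 - t.roc_analysis(pos, neg).auc, abs=1e-12)


class TestIntraSubjectProgression:
    def test_identical_acquisitions_have_zero_cov(self, clean_fit,
                                                  clean_cohort):
        records, _ = clean_cohort
        rec = records[0]
        twin = t.T1MapRecord(map_id="twin", subject_id=rec.subject_id,
                             cohort=rec.cohort, pixels=rec.pixels.copy(),
                             mask=rec.mask.copy(),
                             cp_values=dict(rec.cp_values))
        results = clean_fit.standardise([rec, twin])
        prog, excluded = t.intra_subject_progression(results)
        assert prog[rec.subject_id] == (0.0, 0.0)
        assert excluded == []

    def test_multi_scanner_subject_converges_after_standardisation(
            self, paired_scanner_cohort, scanner_cp):
        records, _ = paired_scanner_cohort
        model = t.fit_pipeline(
            records, t.PipelineSetting("linear", "absolute", "cascaded"),
            [scanner_cp])
        results = model.standardise(records)
        prog, _ = t.intra_subject_progression(results)
        for cov_before, cov_after in prog.values():
            assert cov_before > 0.01   # +100 ms scanner offset
            assert cov_after <= 1e-6   # noise-free: fully harmonised

    def test_single_map_subject_excluded_with_note(self, clean_fit,
                                                   clean_cohort):
        records, _ = clean_cohort
        results = clean_fit.standardise(records[:1])
        prog, excluded = t.intra_subject_progression(results)
        assert prog == {} and excluded == [records[0].subject_id]

    def test_two_mean_cov_oracle(self):
        # subject with per-map means 1000 / 1100 -> COV ~ 0.0673
        assert t.cov([1000.0, 1100.0]) == pytest.approx(0.06734, abs=1e-4)
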