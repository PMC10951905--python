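import numpy as np
import pytest
from hypothesis import given, strategies as st

import t1std as t


class TestCov:
    def test_zero_for_constant_values(self):
        assert t.cov([1100, 1100, 1100]) == 0.0

    def test_matches_direct_formula(self):
        # oracle: sigma = 100 (sample), mu = 1100
        assert t.cov([1000, 1100, 1200]) == pytest.approx(100 / 1100,
                                                          abs=1e-12)

    @given(st.floats(min_value=0.5, max_value=20))
    def test_scale_invariance(self, c):
        base = np.array([1000.0, 1100.0, 1200.0])
        assert t.cov(c * base) == pytest.approx(t.cov(base), rel=1e-9)

    def test_empty_and_zero_mean_rejected(self):
        with pytest.raises(t.ConfigurationError):
            t.cov([])
        with pytest.raises(t.ConfigurationError):
            t.cov([-1.0, 1.0])


class TestEvaluatePipeline:
    def test_cov_of_standardised_means(self, clean_fit, clean_cohort):
        records, _ = clean_cohort
        c = t.evaluate_pipeline(clean_fit, records)
        assert c <= 1e-9  # noise-free cohort standardises perfectly

    def test_two_map_oracle(self, clean_fit, clean_cohort):
        # direct formula on two means 1000 / 1100: sigma = 70.71, mu = 1050
        assert t.cov([1000.0, 1100.0]) == pytest.approx(
            np.std([1000.0, 1100.0], ddof=1) / 1050.0)
        assert t.cov([1000.0, 1100.0]) == pytest.approx(0.06734, abs=1e-4)

    def test_empty_test_set_rejected(self, clean_fit):
        with pytest.raises(t.ConfigurationError):
            t.evaluate_pipeline(clean_fit, [])

    def test_per_subject_averaging(self, clean_fit, clean_cohort):
        records, _ = clean_cohort
        per_map = t.baseline_cov(records, per_subject=False)
        per_subject = t.baseline_cov(records, per_subject=True)
        assert per_map >= 0 and per_subject >= 0


class TestGridEnumeration:
    def test_stage1_has_24_combinations(self):
        settings = t.stage1_settings()
        assert len(settings) == 24
        assert len({(s.regression_type, s.y_type, s.mode)
                    for s in settings}) == 24
        assert all(s.n_bins == 1 for s in settings)

    def test_stage2_has_216_combinations(self):
        top3 = t.stage1_settings()[:3]
        settings = t.stage2_settings(top3)
        assert len(settings) == 216
        assert {s.n_bins for s in settings} == set(range(2, 11))
        assert len({s.cluster_type for s in settings}) == 8

    def test_total_is_240(self):
        assert len(t.stage1_settings()) + \
            len(t.stage2_settings(t.stage1_settings()[:3])) == 240


@pytest.fixture(scope="module")
def grid_report(scanner_cp):
    """Full two-step sweep on a small noise-free two-scanner cohort."""
    seq_cp = t.ConfounderDef(name="sequence", source="0008,103e",
                             representation="categorical",
                             reference_value="S1")
    cps = [scanner_cp, seq_cp]
    kwargs = dict(
        cps=cps, categories={"scanner": ["A", "B"], "sequence": ["S1", "S2"]},
        effects=t.EffectSpec(categorical={
            "scanner": {"B": ("additive", -120.0)},
            "sequence": {"S2": ("additive", 40.0)},
        }),
        noise_pixel_sd=0.0, image_size=16, r_outer=5.0, r_inner=3.0,
    )
    train, _ = t.generate_cohort(14, seed=31, **kwargs)
    test, _ = t.generate_cohort(6, seed=32, design="mixed", **kwargs)
    return t.grid_search(train, test, cps, seed=1), test


class TestGridSearch:
    def test_cardinalities(self, grid_report):
        report, _ = grid_report
        assert len(report.stage1_results) == 24
        assert len(report.stage2_results) == 216
        assert len(report.all_results) == 240

    def test_bpsp_is_overall_minimum(self, grid_report):
        report, _ = grid_report
        covs = [c for _, c, _ in report.all_results if not np.isnan(c)]
        assert report.bpsp_cov == min(covs)
        assert report.bpsp is not None

    def test_bpsp_beats_baseline_on_biased_cohort(self, grid_report):
        report, _ = grid_report
        assert report.bpsp_cov < report.baseline_cov

    def test_worsening_settings_flagged(self, grid_report):
        report, _ = grid_report
        statuses = {st for _, _, st in report.all_results}
        assert "ok" in statuses

    def test_report_csv_and_json(self, grid_report, tmp_path):
        report, _ = grid_report
        report.write(tmp_path / "report.csv", tmp_path / "report.json")
        frame = t.GridSearchReport().to_frame()  # empty frame is fine
        import pandas as pd
        loaded = pd.read_csv(tmp_path / "report.csv")
        assert len(loaded) == 240
        assert set(loaded["stage"]) == {1, 2}
        import json
        summary = json.loads((tmp_path / "report.json").read_text())
        assert summary["n_total"] == 240
        assert summary["bpsp"] is not None
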