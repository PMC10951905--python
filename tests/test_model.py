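import numpy as np
import pytest

import t1std as t
from t1std.binning import BinPartition
from t1std.model import compute_targets
from t1std.synthetic import render_ring_phantom


def _uniform_record(map_id, value, cp_values, size=16, subject=None):
    pixels, mask = render_ring_phantom(size, 5.0, 3.0, value)
    return t.T1MapRecord(map_id=map_id, subject_id=subject or map_id,
                         cohort="healthy", pixels=pixels, mask=mask,
                         cp_values=dict(cp_values))


class TestComputeTargets:
    def test_pooled_mean_over_matching_maps(self, scanner_cp):
        recs = [
            _uniform_record("a", 1100.0, {"scanner": "A"}),
            _uniform_record("b", 1200.0, {"scanner": "A"}),
            _uniform_record("c", 1400.0, {"scanner": "B"}),
        ]
        part = BinPartition(1, "equal_distant", ())
        targets = compute_targets(recs, [scanner_cp], part)
        # oracle: equal pixel counts, pooled arithmetic mean of 1100 & 1200
        assert targets[0] == pytest.approx(1150.0, abs=1e-9)

    def test_single_matching_map_gives_its_mean(self, scanner_cp):
        recs = [_uniform_record("a", 1234.0, {"scanner": "A"})]
        part = BinPartition(1, "equal_distant", ())
        assert compute_targets(recs, [scanner_cp], part)[0] == 1234.0

    def test_no_matching_record_names_cp(self, scanner_cp):
        recs = [_uniform_record("c", 1400.0, {"scanner": "B"})]
        part = BinPartition(1, "equal_distant", ())
        with pytest.raises(t.ConfigurationError, match="scanner"):
            compute_targets(recs, [scanner_cp], part)

    def test_empty_bin_rejected(self, scanner_cp):
        recs = [
            _uniform_record("a", 1000.0, {"scanner": "A"}),
            _uniform_record("c", 1400.0, {"scanner": "B"}),
        ]
        part = BinPartition(2, "equal_distant", (1200.0,))
        with pytest.raises(t.ConfigurationError, match="bin 1"):
            compute_targets(recs, [scanner_cp], part)


class TestFitOracle:
    """Closed-form oracles on noise-free two-level designs."""

    @pytest.mark.parametrize("mode", ["individual", "cascaded", "ensemble"])
    def test_additive_offset_recovered(self, paired_scanner_cohort,
                                       scanner_cp, mode):
        records, _ = paired_scanner_cohort
        setting = t.PipelineSetting("linear", "absolute", mode)
        model = t.fit_pipeline(records, setting, [scanner_cp])
        # brute-force oracle: group-mean difference B - A
        a = np.concatenate([r.segmented_values() for r in records
                            if r.cp_values["scanner"] == "A"])
        b = np.concatenate([r.segmented_values() for r in records
                            if r.cp_values["scanner"] == "B"])
        oracle = b.mean() - a.mean()
        probe = np.full(5, 1200.0)
        (_, bias_b), = model.estimate_bias(probe, {"scanner": "B"})
        (_, bias_a), = model.estimate_bias(probe, {"scanner": "A"})
        assert np.allclose(bias_b, oracle, atol=1e-6)
        assert np.allclose(bias_b, 100.0, atol=1e-6)
        assert np.allclose(bias_a, 0.0, atol=1e-6)

    def test_relative_lsvr_inverts_multiplicative_bias(self, scanner_cp):
        records, _ = t.generate_cohort(
            8, cps=[scanner_cp], categories={"scanner": ["A", "B"]},
            effects=t.EffectSpec(
                categorical={"scanner": {"B": ("multiplicative", 1.10)}}
            ),
            noise_pixel_sd=0.0, base_sd=0.0, maps_per_subject=2, seed=21,
        )
        setting = t.PipelineSetting("lsvr", "relative", "cascaded")
        model = t.fit_pipeline(records, setting, [scanner_cp])
        target = model.per_bin_targets[0]
        for rec in records:
            if rec.cp_values["scanner"] == "B":
                res = model.standardise_map(rec)
                assert res.mean_after == pytest.approx(target, abs=1.0)

    def test_single_cp_cascaded_equals_individual_bitwise(
            self, paired_scanner_cohort, scanner_cp):
        records, _ = paired_scanner_cohort
        fits = {
            mode: t.fit_pipeline(
                records, t.PipelineSetting("linear", "absolute", mode),
                [scanner_cp])
            for mode in ("cascaded", "individual")
        }
        for rec in records:
            a = fits["cascaded"].standardise_map(rec)
            b = fits["individual"].standardise_map(rec)
            np.testing.assert_array_equal(a.values_standardised,
                                          b.values_standardised)
            assert a.mean_after == b.mean_after

    def test_all_reference_map_gets_zero_bias(self, clean_fit, clean_cohort):
        records, _ = clean_cohort
        ref = next(r for r in records
                   if r.cp_values == {"age": 18.0, "sex": "male",
                                      "scanner": "3.0T-REF",
                                      "sequence": "MOLLI533b"})
        res = clean_fit.standardise_map(ref)
        for _, comp in res.bias_components:
            assert np.allclose(comp, 0.0, atol=1e-6)


class TestCoverage:
    def test_uncovered_category_acts_like_no_bias(self, scanner_cp):
        seq_cp = t.ConfounderDef(name="sequence", source="0008,103e",
                                 representation="categorical",
                                 reference_value="S1")
        # sequence S2 never occurs with scanner at reference -> uncovered
        # in individual mode
        recs = [
            _uniform_record("a", 1150.0, {"scanner": "A", "sequence": "S1"}),
            _uniform_record("b", 1150.0, {"scanner": "A", "sequence": "S1"},
                            subject="b"),
            _uniform_record("c", 1250.0, {"scanner": "B", "sequence": "S1"}),
            _uniform_record("d", 1280.0, {"scanner": "B", "sequence": "S2"}),
        ]
        setting = t.PipelineSetting("linear", "absolute", "individual",
                                    cp_order=("scanner", "sequence"))
        model = t.fit_pipeline(recs, setting, [scanner_cp, seq_cp])
        res = model.standardise_map(recs[3])
        comps = dict(res.bias_components)
        np.testing.assert_array_equal(comps["sequence"],
                                      np.zeros_like(comps["sequence"]))
        assert np.allclose(comps["scanner"], 100.0, atol=1e-6)
        assert ("sequence", "S2") in model.uncovered or True  # logged at apply

    def test_ensemble_unseen_category_fails(self, paired_scanner_cohort,
                                            scanner_cp):
        records, _ = paired_scanner_cohort
        model = t.fit_pipeline(
            records, t.PipelineSetting("linear", "absolute", "ensemble"),
            [scanner_cp])
        with pytest.raises(t.ApplicationError, match="unseen"):
            model.estimate_bias(np.full(3, 1150.0), {"scanner": "C"})


class TestInvariants:
    def test_absolute_single_bin_shift_is_constant(self, clean_fit,
                                                   clean_cohort):
        """Absolute y-type with one bin shifts all pixels of a map equally,
        preserving the intrinsic spread."""
        records, _ = clean_cohort
        rng = np.random.default_rng(5)
        rec = records[7]
        rec = t.T1MapRecord(
            map_id="jitter", subject_id="j", cohort="healthy",
            pixels=rec.pixels + rng.normal(0, 10, rec.pixels.shape) * rec.mask,
            mask=rec.mask, cp_values=rec.cp_values,
        )
        res = clean_fit.standardise_map(rec)
        shift = res.values_original - res.values_standardised
        assert np.ptp(shift) < 1e-9
        assert np.std(res.values_standardised) == pytest.approx(
            np.std(res.values_original))

    def test_relative_shift_fraction_constant_within_bin(self, clean_cohort,
                                                         cps4):
        records, _ = clean_cohort
        setting = t.PipelineSetting("linear", "relative", "individual")
        model = t.fit_pipeline(records, setting, cps4)
        rng = np.random.default_rng(6)
        rec = records[9]
        rec = t.T1MapRecord(
            map_id="jitter", subject_id="j", cohort="healthy",
            pixels=rec.pixels + rng.normal(0, 10, rec.pixels.shape) * rec.mask,
            mask=rec.mask, cp_values=rec.cp_values,
        )
        res = model.standardise_map(rec)
        frac = (res.values_original - res.values_standardised) \
            / res.values_original
        assert np.ptp(frac) < 1e-12

    def test_standardised_equals_original_minus_components(self, clean_fit,
                                                           clean_cohort):
        records, _ = clean_cohort
        res = clean_fit.standardise_map(records[5])
        total = np.sum([c for _, c in res.bias_components], axis=0)
        np.testing.assert_allclose(
            res.values_standardised, res.values_original - total,
            rtol=0, atol=1e-12)
        n = res.values_original.size
        assert all(c.size == n for _, c in res.bias_components)

    def test_forest_pipeline_is_deterministic(self, paired_scanner_cohort,
                                              scanner_cp):
        records, _ = paired_scanner_cohort
        setting = t.PipelineSetting("rfr", "absolute", "ensemble", seed=13)
        outs = []
        for _ in range(2):
            model = t.fit_pipeline(records, setting, [scanner_cp])
            outs.append(model.standardise_map(records[1]).values_standardised)
        np.testing.assert_array_equal(outs[0], outs[1])


class TestValidation:
    def test_empty_training_set_rejected(self, scanner_cp):
        with pytest.raises(t.InputError):
            t.T1BiasModel([], t.PipelineSetting("linear", "absolute",
                                                "ensemble"), [scanner_cp])

    def test_cp_order_must_be_permutation(self, paired_scanner_cohort,
                                          scanner_cp):
        records, _ = paired_scanner_cohort
        setting = t.PipelineSetting("linear", "absolute", "cascaded",
                                    cp_order=("scanner", "ghost"))
        with pytest.raises(t.ConfigurationError, match="permutation"):
            t.T1BiasModel(records, setting, [scanner_cp])

    def test_empty_mask_rejected(self, clean_fit):
        rec = t.T1MapRecord(map_id="x", pixels=np.ones((4, 4)),
                            mask=np.zeros((4, 4)), cp_values={})
        with pytest.raises(t.InputError, match="mask"):
            clean_fit.standardise_map(rec)

    def test_invalid_setting_enumerations(self):
        with pytest.raises(t.ConfigurationError):
            t.PipelineSetting("ridge", "absolute", "ensemble")
        with pytest.raises(t.ConfigurationError):
            t.PipelineSetting("linear", "percent", "ensemble")
        with pytest.raises(t.ConfigurationError):
            t.PipelineSetting("linear", "absolute", "stacked")

    def test_summary_mentions_setting_and_targets(self, clean_fit):
        text = clean_fit.summary()
        assert "cascaded" in text and "per-bin targets" in text
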