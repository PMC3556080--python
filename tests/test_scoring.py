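import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sirna_sensitizer.scoring import (
    HitThresholds,
    bh_adjust,
    bonferroni_adjust,
    call_primary_hits,
    compute_si,
    fit_drug_effect,
    normalize_to_gl2,
    score_screen,
    select_best_sirnas,
    squeeze_var,
    validate_hits_deconvolution,
    drug_specificity_matrix,
    zprime_factor,
)
from sirna_sensitizer.synthetic import ScreenSimConfig, generate_screen_dataset

from conftest import bh_stepup_oracle


class TestNormalization:
    def test_gl2_median_divides_each_well(self, small_plate_table):
        norm = normalize_to_gl2(small_plate_table)
        # GL2 wells {80..120} have median 100; a 50-unit well would score 0.5
        veh = norm[(norm["plate_id"] == "P1_vehicle") & (norm["gene"] == "G01")]
        assert np.allclose(veh["norm_value"], 0.9)
        gl2 = norm[norm["is_control"] & (norm["plate_id"] == "P1_vehicle")]
        assert np.isclose(gl2["norm_value"].median(), 1.0)

    def test_all_wells_at_gl2_median_normalize_to_one(self):
        rows = [
            dict(plate_id="P", well=f"A{i + 1:02d}", gene=g, sirna_id=g,
                 condition="vehicle", drug="", raw_value=100.0)
            for i, g in enumerate(["GL2"] * 3 + ["G01", "G02"])
        ]
        norm = normalize_to_gl2(pd.DataFrame(rows))
        assert np.allclose(norm["norm_value"], 1.0)

    def test_scale_invariance_per_plate(self, noiseless_planted_screen):
        _, measurements, _ = noiseless_planted_screen
        scaled = measurements.copy()
        plate = scaled["plate_id"].unique()[0]
        scaled.loc[scaled["plate_id"] == plate, "raw_value"] *= 37.5
        a = normalize_to_gl2(measurements)["norm_value"]
        b = normalize_to_gl2(scaled)["norm_value"]
        assert np.allclose(a, b)

    def test_non_positive_gl2_median_is_fatal(self, small_plate_table):
        bad = small_plate_table.copy()
        with pytest.raises(ValueError, match="plates without"):
            normalize_to_gl2(bad[bad["gene"] != "GL2"])


class TestSensitizationIndex:
    def test_identical_arms_give_si_one(self, noiseless_null_screen):
        _, measurements, _ = noiseless_null_screen
        si = compute_si(normalize_to_gl2(measurements))
        assert np.allclose(si["si"], 1.0)
        assert np.allclose(si["log2_si"], 0.0)

    def test_si_formula_direct_evaluation(self, small_plate_table):
        # V_drug=40, GL2_drug median=80 -> 0.5 ; V_DMSO=90, GL2_DMSO median=100 -> 0.9
        table = small_plate_table.copy()
        table.loc[(table["plate_id"] == "P1_drug") & (table["gene"] == "GL2"),
                  "raw_value"] = [60.0, 70.0, 80.0, 90.0, 100.0]
        si = compute_si(normalize_to_gl2(table))
        g1 = si.loc[si["gene"] == "G01", "si"].item()
        assert np.isclose(g1, (40 / 80) / (90 / 100))
        assert np.isclose(g1, 0.5556, atol=1e-4)

    def test_planted_factor_recovered_exactly(self, noiseless_planted_screen):
        _, measurements, _ = noiseless_planted_screen
        si = compute_si(normalize_to_gl2(measurements))
        assert np.isclose(si.loc[si["gene"] == "G05", "si"].item(), 0.5, atol=1e-12)
        others = si.loc[si["gene"] != "G05", "si"]
        assert np.allclose(others, 1.0, atol=1e-12)

    def test_si_below_threshold_means_drop_over_15_percent(self):
        # SI < 0.85 is the same statement as a >15 % viability drop under drug
        thresholds = HitThresholds()
        rec = pd.DataFrame({"gene": ["a", "b"], "si": [0.849, 0.851],
                            "fdr": [0.0, 0.0]})
        flagged = call_primary_hits(rec, thresholds)
        drop = 1.0 - rec["si"]
        assert list(flagged["primary_hit"]) == list(drop > 0.15)


class TestZPrime:
    def test_noiseless_maximum(self):
        assert zprime_factor([20.0, 20.0], [100.0, 100.0]) == 1.0

    def test_textbook_arithmetic(self):
        pos = np.array([15.0, 20.0, 25.0])  # mean 20, sd 5
        neg = np.array([95.0, 100.0, 105.0])  # mean 100, sd 5
        z = zprime_factor(pos, neg)
        assert np.isclose(z, 1 - 30 / 80)  # 0.625, a passing window
        assert z >= 0.5

    def test_monotone_in_noise(self):
        pos = np.array([15.0, 20.0, 25.0])
        neg = np.array([95.0, 100.0, 105.0])
        wider = zprime_factor(pos * 1 + (pos - 20) * 1, neg)  # double pos spread
        assert wider < zprime_factor(pos, neg)

    def test_equal_means_fail_gate(self):
        assert zprime_factor([1.0, 2.0], [1.0, 2.0]) == float("-inf")


class TestDrugEffectModel:
    def test_identical_arms_give_p_one(self, noiseless_null_screen):
        _, measurements, _ = noiseless_null_screen
        fit = fit_drug_effect(normalize_to_gl2(measurements), moderate=False)
        assert np.allclose(fit["p_value"], 1.0)

    def test_unmoderated_model_equals_pooled_t_test(self):
        # two-plate screen, 4 replicates/arm, random values per gene
        rng = np.random.default_rng(42)
        values = {}
        for g in ["G01", "G02", "G03"]:
            values[g] = (rng.lognormal(0, 0.2, 4), rng.lognormal(-0.3, 0.2, 4))
        rows = []
        widx = 0
        for plate, cond, drug in [("P_vehicle", "vehicle", ""), ("P_drug", "drug", "IM")]:
            for v in [100.0] * 3:
                rows.append(dict(plate_id=plate, well=f"A{widx % 24 + 1:02d}", gene="GL2",
                                 sirna_id="GL2", condition=cond, drug=drug,
                                 plate_pair="P", raw_value=v))
                widx += 1
            for g, (veh, drg) in values.items():
                for v in (veh if cond == "vehicle" else drg):
                    rows.append(dict(plate_id=plate, well=f"B{widx % 24 + 1:02d}", gene=g,
                                     sirna_id="pooled", condition=cond, drug=drug,
                                     plate_pair="P", raw_value=float(v) * 100))
                    widx += 1
        fit = fit_drug_effect(normalize_to_gl2(pd.DataFrame(rows)), moderate=False)
        for g, (veh, drg) in values.items():
            t_ref, p_ref = stats.ttest_ind(np.log2(drg), np.log2(veh), equal_var=True)
            row = fit[fit["gene"] == g]
            assert np.isclose(row["t"].item(), t_ref, atol=1e-10)
            assert np.isclose(row["p_value"].item(), p_ref, atol=1e-10)

    def test_planted_noiseless_effect_p_below_floor(self, noiseless_planted_screen):
        _, measurements, _ = noiseless_planted_screen
        fit = fit_drug_effect(normalize_to_gl2(measurements))
        assert fit.loc[fit["gene"] == "G05", "p_value"].item() < 1e-30

    def test_moderation_shrinks_variances_toward_prior(self):
        rng = np.random.default_rng(7)
        s2 = rng.chisquare(4, size=200) / 4 * 0.04
        s2_post, prior_df, prior_s2 = squeeze_var(s2, 4.0)
        assert prior_df > 0
        # shrinkage pulls extremes toward the prior value
        assert s2_post.std() < s2.std()
        assert np.all(s2_post > 0)


class TestMultipleTesting:
    def test_bh_matches_hand_stepup(self):
        fdr = bh_adjust([0.01, 0.02, 0.5])
        assert np.allclose(fdr, [0.03, 0.03, 0.5])

    def test_all_ones_stay_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=100))
    def test_bh_matches_brute_force_oracle(self, p):
        assert np.allclose(bh_adjust(p), bh_stepup_oracle(p), atol=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    def test_bh_bounds_and_monotonicity(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0 + 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_invalid_p_is_fatal(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bonferroni_adjust([-0.1])

    def test_bonferroni_arithmetic(self):
        assert np.isclose(bonferroni_adjust([0.01], m=5)[0], 0.05)
        assert bonferroni_adjust([0.5], m=10)[0] == 1.0
        assert bonferroni_adjust([0.37], m=1)[0] == 0.37


class TestHitCalling:
    @pytest.mark.parametrize(
        "si,fdr,expected",
        [(0.80, 0.10, True), (0.80, 0.20, False), (0.85, 0.10, False),
         (0.90, 0.10, False), (0.80, 0.15, False)],
    )
    def test_dual_criterion_with_strict_boundaries(self, si, fdr, expected):
        rec = pd.DataFrame({"gene": ["g"], "si": [si], "fdr": [fdr]})
        assert call_primary_hits(rec)["primary_hit"].item() == expected

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        si=st.floats(min_value=0.01, max_value=1.5),
        fdr=st.floats(min_value=0.0, max_value=1.0),
        d_si=st.floats(min_value=0.0, max_value=0.5),
        d_fdr=st.floats(min_value=0.0, max_value=0.5),
    )
    def test_hit_flag_is_monotone(self, si, fdr, d_si, d_fdr):
        """Lowering SI or FDR never un-calls a hit."""
        base = call_primary_hits(
            pd.DataFrame({"gene": ["g"], "si": [si], "fdr": [fdr]})
        )["primary_hit"].item()
        better = call_primary_hits(
            pd.DataFrame({"gene": ["g"], "si": [max(si - d_si, 1e-9)],
                          "fdr": [max(fdr - d_fdr, 0.0)]})
        )["primary_hit"].item()
        assert better or not base

    def test_noiseless_hits_equal_planted_truth(self, noiseless_planted_screen):
        _, measurements, truth = noiseless_planted_screen
        rec = score_screen(measurements)
        hits = set(rec.loc[rec["primary_hit"], "gene"])
        planted = set(truth.loc[truth["is_sensitizer"], "gene"])
        assert hits == planted == {"G05"}


class TestDeconvolution:
    @staticmethod
    def _deconv_records(confirming):
        rows = []
        for k in range(4):
            rows.append(dict(gene="G01", drug="IM", sirna_id=f"G01_si{k + 1}",
                             si=0.5 if k in confirming else 1.0,
                             fdr=0.01 if k in confirming else 0.9))
        return pd.DataFrame(rows)

    def test_two_of_four_validates(self):
        out = validate_hits_deconvolution(self._deconv_records({0, 1}))
        assert out["validated_hit"].item()
        assert out["n_confirming_sirnas"].item() == 2

    def test_one_of_four_does_not_validate(self):
        out = validate_hits_deconvolution(self._deconv_records({2}))
        assert not out["validated_hit"].item()
        assert out["n_confirming_sirnas"].item() == 1

    def test_short_sirna_panel_warns(self, caplog):
        rec = self._deconv_records({0, 1}).iloc[:3]
        with caplog.at_level("WARNING"):
            out = validate_hits_deconvolution(rec)
        assert "only 3 siRNAs" in caplog.text
        assert out["validated_hit"].item()  # still >= 2 confirming

    def test_best_sirna_selection_is_lowest_si(self):
        rec = self._deconv_records({0, 1})
        best = select_best_sirnas(rec, "IM", n=2)
        assert set(best["G01"]) == {"G01_si1", "G01_si2"}


class TestSpecificity:
    def test_single_gene_single_drug(self):
        rec = pd.DataFrame({"gene": ["G01"], "drug": ["IM"], "si": [0.7], "fdr": [0.01]})
        si_m, hit_m, counts = drug_specificity_matrix(rec)
        assert si_m.shape == (1, 1)
        assert counts["IM"] == 1

    def test_noiseless_panel_counts_match_planted_truth(self):
        """14/17, 5/17 and 0/17 sensitizer pattern across a three-drug panel."""
        genes = [f"G{i + 1:02d}" for i in range(17)]
        planted = {"sunitinib": genes[:14], "doxorubicin": genes[:5], "ifosfamide": []}
        cfg = ScreenSimConfig(
            seed=21, n_genes=17, noise_sd=0.0, plate_effect_sd=0.0,
            drugs={"sunitinib": 0.7, "doxorubicin": 0.7, "ifosfamide": 0.7},
            sensitizer_genes=planted,
        )
        measurements, truth = generate_screen_dataset(cfg)
        rec = score_screen(measurements)
        _, hit_m, counts = drug_specificity_matrix(rec)
        assert counts["sunitinib"] == 14
        assert counts["doxorubicin"] == 5
        assert counts["ifosfamide"] == 0
        for drug, sub in truth.groupby("drug"):
            called = set(hit_m.index[hit_m[drug]])
            assert called == set(sub.loc[sub["is_sensitizer"], "gene"])
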