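"""Lipidomics normalization and Kruskal-Wallis (vs a permutation oracle),
species grammar, chain classification, and 2^-ddCt qPCR analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crgpipe import lipidqpcr as lq
from crgpipe import synthio
from oracles import kruskal_exact_p_by_permutation, kruskal_h_by_hand


class TestSpeciesGrammar:
    @pytest.mark.parametrize(
        "text,cls,carbons,db,hyd",
        [
            ("PI 34:1", "PI", 34, 1, None),
            ("PC 36:2", "PC", 36, 2, None),
            ("IPC-C 44:0", "IPC", 44, 0, 3),
            ("MIPC-B 42:0", "MIPC", 42, 0, 2),
            ("MIPC-D 46:0", "MIPC", 46, 0, 4),
        ],
    )
    def test_parse(self, text, cls, carbons, db, hyd):
        sp = lq.parse_species(text)
        assert (sp.lipid_class, sp.carbons, sp.double_bonds, sp.hydroxyls) == (
            cls, carbons, db, hyd,
        )
        assert sp.name == text

    def test_hydroxylation_restricted_to_sphingolipids(self):
        with pytest.raises(ValueError):
            lq.parse_species("PC-B 34:1")

    @pytest.mark.parametrize("bad", ["PI", "34:1", "PI 34", "PI x:y"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            lq.parse_species(bad)


class TestNormalization:
    def make_tables(self):
        intensities = pd.DataFrame(
            {"s1": [500.0, 80.0], "s2": [250.0, 40.0]},
            index=["PI 34:1", "IPC-C 44:0"],
        )
        standards = pd.DataFrame(
            {"s1": [250.0, 80.0], "s2": [250.0, 40.0]}, index=["PI", "IPC"]
        )
        return intensities, standards

    def test_ratio_to_class_standard(self):
        intensities, standards = self.make_tables()
        normed = lq.normalize_to_standards(intensities, standards)
        assert normed.loc["PI 34:1", "s1"] == 2.0
        assert normed.loc["IPC-C 44:0", "s1"] == 1.0

    def test_missing_standard_names_species(self):
        intensities, standards = self.make_tables()
        with pytest.raises(ValueError, match="PI"):
            lq.normalize_to_standards(intensities, standards.drop("PI"))

    def test_zero_standard_names_sample(self):
        intensities, standards = self.make_tables()
        standards.loc["IPC", "s2"] = 0.0
        with pytest.raises(ValueError, match="s2"):
            lq.normalize_to_standards(intensities, standards)

    @given(st.floats(0.1, 100.0))
    def test_scale_invariance_per_sample(self, c):
        intensities, standards = self.make_tables()
        scaled_i, scaled_s = intensities.copy(), standards.copy()
        scaled_i["s1"] *= c
        scaled_s["s1"] *= c
        pd.testing.assert_frame_equal(
            lq.normalize_to_standards(intensities, standards),
            lq.normalize_to_standards(scaled_i, scaled_s),
        )

    def test_cv_zero_simulation_round_trip(self):
        species = [lq.parse_species("PI 34:1"), lq.parse_species("IPC-C 44:0")]
        spec = synthio.LipidSimSpec(
            species=species,
            group_means={"PI 34:1": {"drug": 200.0, "DMSO": 100.0},
                         "IPC-C 44:0": {"drug": 50.0, "DMSO": 50.0}},
            standard_intensity={"PI": 100.0, "IPC": 25.0},
            cv=0.0, seed=0,
        )
        intensities, standards, truth = synthio.simulate_lipidome(spec)
        normed = lq.normalize_to_standards(intensities, standards)
        for r in truth.itertuples():
            cols = [c for c in normed.columns if c.startswith(r.group)]
            np.testing.assert_allclose(normed.loc[r.species, cols], r.mean_normalized)


class TestLog2Response:
    def test_doubling_gives_plus_one(self):
        normed = pd.DataFrame({"drug_0": [2.0], "DMSO_0": [1.0]}, index=["PI 34:1"])
        resp = lq.lipid_log2_response(normed, {"drug_0": "drug", "DMSO_0": "DMSO"})
        assert resp.iloc[0] == pytest.approx(1.0)

    def test_quartering_gives_minus_two(self):
        normed = pd.DataFrame({"d": [0.25], "c": [1.0]}, index=["PI 34:1"])
        resp = lq.lipid_log2_response(normed, {"d": "drug", "c": "DMSO"})
        assert resp.iloc[0] == pytest.approx(-2.0)

    def test_zero_mean_flagged_nan(self):
        normed = pd.DataFrame({"d": [0.0], "c": [1.0]}, index=["x 1:0"])
        resp = lq.lipid_log2_response(normed, {"d": "drug", "c": "DMSO"})
        assert np.isnan(resp.iloc[0])


class TestKruskalWallis:
    def test_hand_worked_case(self):
        h, _ = lq.kruskal_wallis([[1, 2, 3], [4, 5, 6]], exact="never")
        assert h == pytest.approx(3.857, abs=1e-3)

    def test_identical_groups_h_zero_p_one(self):
        assert lq.kruskal_wallis([[5, 5, 5], [5, 5, 5]]) == (0.0, 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            lq.kruskal_wallis([[1, 2], []])

    @pytest.mark.parametrize(
        "groups",
        [
            [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]],
            [[1.0, 3.0], [2.0, 4.0], [5.0, 6.0]],
            [[1.0, 1.0, 2.0], [2.0, 3.0, 3.0]],  # ties across groups
            [[10.0, 2.0, 8.0], [4.0, 6.0, 1.0, 7.0]],
        ],
    )
    def test_matches_permutation_oracle(self, groups):
        h_oracle, p_oracle = kruskal_exact_p_by_permutation(groups)
        h, p = lq.kruskal_wallis(groups, exact="always")
        assert h == pytest.approx(h_oracle, abs=1e-9)
        assert p == pytest.approx(p_oracle, abs=1e-9)

    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=4),
        st.lists(st.floats(-50, 50), min_size=2, max_size=4),
    )
    def test_h_formula_matches_hand_computation(self, g1, g2):
        h, _ = lq.kruskal_wallis([g1, g2], exact="never")
        assert h == pytest.approx(kruskal_h_by_hand([g1, g2]), abs=1e-9)


class TestChainClassification:
    @pytest.mark.parametrize(
        "text,cutoff,length,saturated",
        [
            ("PI 32:0", 32, "short", True),
            ("PC 36:2", 32, "long", False),
            ("PI 34:1", 32, "long", False),
            ("PE 28:0", 32, "short", True),
        ],
    )
    def test_rule(self, text, cutoff, length, saturated):
        cc = lq.classify_chain(lq.parse_species(text), cutoff)
        assert (cc.length, cc.saturated) == (length, saturated)

    def test_zero_cutoff_everything_long(self):
        assert lq.classify_chain(lq.parse_species("PE 28:0"), 0).length == "long"


class TestDdct:
    def make_ct(self):
        rows = []
        for cond, tgt in [("treated", 20.0), ("DMSO", 22.0)]:
            for rep in range(3):
                sample = f"{cond}_{rep}"
                rows.append(("CRG1", sample, cond, tgt))
                rows.append(("ACT1", sample, cond, 15.0))
        return pd.DataFrame(rows, columns=["gene", "sample", "condition", "ct"])

    def test_worked_fold_change(self):
        fold = lq.ddct_fold_change(self.make_ct(), calibrator_condition="DMSO")
        assert fold.loc["CRG1", "treated"] == pytest.approx(4.0)  # ddCt = -2
        assert fold.loc["CRG1", "DMSO"] == pytest.approx(1.0)

    def test_missing_reference_rejected(self):
        ct = self.make_ct()
        ct = ct[ct["gene"] != "ACT1"]
        with pytest.raises(ValueError):
            lq.ddct_fold_change(ct)

    def test_per_sample_ct_shift_cancels(self):
        ct = self.make_ct()
        shifted = ct.copy()
        shifted.loc[shifted["sample"] == "treated_0", "ct"] += 3.0
        pd.testing.assert_frame_equal(
            lq.ddct_fold_change(ct), lq.ddct_fold_change(shifted)
        )

    def test_simulated_fold_recovered(self):
        spec = synthio.QpcrSimSpec(
            genes=["CRG1"], conditions=["DMSO", "treated"],
            true_log2_fold={("CRG1", "treated"): np.log2(40.0)},
            ct_sd=0.0, sample_offset_sd=0.5, seed=11,
        )
        fold = lq.ddct_fold_change(synthio.simulate_qpcr(spec))
        assert fold.loc["CRG1", "treated"] == pytest.approx(40.0, rel=1e-6)


class TestQpcrTest:
    def test_identical_vectors_p_one(self):
        t, p, degenerate = lq.qpcr_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
        assert (t, p, degenerate) == (0.0, 1.0, True)

    def test_constant_shift_flagged_with_warning(self):
        with pytest.warns(RuntimeWarning):
            t, p, degenerate = lq.qpcr_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0], paired=True)
        assert p == 0.0 and degenerate

    def test_paired_and_unpaired_agree_with_scipy_conventions(self):
        a, b = [1.0, 2.5, 3.0, 4.2], [1.5, 2.0, 2.2, 3.0]
        t_p, p_p, _ = lq.qpcr_test(a, b, paired=True)
        t_u, p_u, _ = lq.qpcr_test(a, b, paired=False)
        assert 0 < p_p < 1 and 0 < p_u < 1 and t_p != t_u

    def test_null_calibration(self):
        rng = np.random.default_rng(17)
        rejections = 0
        trials = 400
        for _ in range(trials):
            a = rng.normal(0, 1, 6)
            b = rng.normal(0, 1, 6)
            _, p, _ = lq.qpcr_test(a, b, paired=True)
            rejections += p < 0.05
        assert rejections / trials == pytest.approx(0.05, abs=0.03)
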