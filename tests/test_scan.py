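import numpy as np
import pandas as pd
import pytest

from rootqtl import GenotypePanel
from rootqtl.scan import (MLMSpec, MarkerScanEngine, cross_validate,
                          fit_marker_model, lod_from_p, merge_to_qtl,
                          multilocus_scan, permutation_threshold,
                          variance_explained, MultilocusResult)
from rootqtl.simulate import (PanelConfig, PhenoDesign, PlantedQTL,
                              simulate_panel, simulate_phenotypes)


def quiet_design(seed, noise=0.2):
    vc = {t: dict(V_G=0.1, V_GxT=0.02, V_GxY=0.02, V_GxTxY=0.0, V_rep=0.0,
                  V_E=noise)
          for t in ("Rdw", "Rl", "Sdw", "Til", "RS")}
    return PhenoDesign(variance_components=vc, seed=seed)


class TestLodFromP:
    @pytest.mark.parametrize("p,lod", [(1e-4, 4.0), (1.0, 0.0),
                                       (0.05, 1.3010)])
    def test_closed_form(self, p, lod):
        assert lod_from_p(p) == pytest.approx(lod, abs=1e-4)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            lod_from_p(bad)


class TestFitMarkerModel:
    def test_strong_planted_qtl_highly_significant(self, small_panel):
        marker = small_panel.marker_ids[25]
        qtl = PlantedQTL(marker, "Rdw", main_effect=3.0)
        pheno = simulate_phenotypes(small_panel, [qtl], quiet_design(seed=2))
        rec = fit_marker_model(pheno, small_panel, marker, trait="Rdw")
        assert rec["p_M"] < 1e-10

    def test_gxt_only_effect_loads_on_interaction(self, small_panel):
        marker = small_panel.marker_ids[30]
        qtl = PlantedQTL(marker, "Rdw", main_effect=-1.0, gxt_effect=2.0)
        pheno = simulate_phenotypes(small_panel, [qtl], quiet_design(seed=4))
        rec = fit_marker_model(pheno, small_panel, marker, trait="Rdw")
        assert rec["p_MxT"] < 1e-6
        assert rec["p_MxT"] < rec["p_M"] * 1e-3

    def test_monomorphic_marker_skipped_with_reason(self, small_pheno,
                                                    small_panel):
        panel = GenotypePanel(
            small_panel.genotype_ids, small_panel.subpops,
            np.zeros((small_panel.n_genotypes, 1)),
            pd.DataFrame({"marker": ["mono"], "chromosome": ["1H"],
                          "cM": [1.0]}))
        rec = fit_marker_model(small_pheno, panel, "mono", trait="Rdw",
                               spec=MLMSpec(n_pcs=0))
        assert rec["reason"] == "monomorphic" and rec["p_M"] == 1.0

    def test_null_pvalues_uniform(self):
        """Calibration: p of an independent marker over repeated null
        phenotype draws is approximately uniform (KS test)."""
        from scipy import stats

        panel = simulate_panel(PanelConfig(
            n_genotypes=80, subpop_sizes={"cultivar": 27, "landrace": 27,
                                          "wild": 26},
            n_markers=60, seed=8, missing_rate=0.0))
        marker = panel.marker_ids[10]
        pvals = []
        for s in range(300):
            pheno = simulate_phenotypes(panel, [], quiet_design(seed=s,
                                                                noise=1.0))
            eng = MarkerScanEngine(panel, pheno, "Rdw", MLMSpec(n_pcs=2))
            rec = eng.test_marker(panel.marker_index(marker))
            pvals.append(rec["p_M"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_kinship_whitening_runs(self, small_panel):
        marker = small_panel.marker_ids[25]
        qtl = PlantedQTL(marker, "Rdw", main_effect=3.0)
        pheno = simulate_phenotypes(small_panel, [qtl], quiet_design(seed=2))
        rec = fit_marker_model(pheno, small_panel, marker, trait="Rdw",
                               spec=MLMSpec(use_kinship=True))
        assert rec["p_M"] < 1e-6


class TestPermutationThreshold:
    def test_alpha_one_is_minimum_of_max_lods(self, small_panel, small_pheno):
        thr = permutation_threshold(small_pheno, small_panel, "Rdw",
                                    n_perm=50, alpha=1.0 - 1e-12, seed=1)
        assert thr.threshold == pytest.approx(thr.max_lods.min())

    def test_duplicated_records_leave_threshold_unchanged(self, small_panel,
                                                          small_pheno):
        a = permutation_threshold(small_pheno, small_panel, "Til",
                                  n_perm=50, seed=3)
        doubled = pd.concat([small_pheno, small_pheno], ignore_index=True)
        b = permutation_threshold(doubled, small_panel, "Til",
                                  n_perm=50, seed=3)
        assert a.threshold == pytest.approx(b.threshold)

    def test_threshold_grows_with_marker_count(self, small_panel,
                                               small_pheno):
        few = small_panel.subset_markers(small_panel.marker_ids[:40])
        a = permutation_threshold(small_pheno, few, "Rdw", n_perm=100, seed=5)
        b = permutation_threshold(small_pheno, small_panel, "Rdw",
                                  n_perm=100, seed=5)
        assert b.threshold >= a.threshold

    def test_floor_applied(self, small_panel, small_pheno):
        thr = permutation_threshold(small_pheno, small_panel, "Rdw",
                                    n_perm=50, alpha=0.9, seed=2)
        assert thr.effective >= 4.0

    def test_too_few_permutations_rejected(self, small_panel, small_pheno):
        with pytest.raises(ValueError):
            permutation_threshold(small_pheno, small_panel, "Rdw", n_perm=5)


class TestMultilocusScan:
    def test_recovers_three_unlinked_qtl(self, small_panel):
        from rootqtl.simulate import choose_qtl_markers

        markers = choose_qtl_markers(small_panel, 3, seed=13)
        qtls = [PlantedQTL(m, "Rdw", main_effect=2.5) for m in markers]
        pheno = simulate_phenotypes(small_panel, qtls, quiet_design(seed=13))
        res = multilocus_scan(pheno, small_panel, "Rdw", MLMSpec(),
                              threshold=4.0)
        mm = small_panel.marker_map.set_index("marker")
        for m in markers:
            chrom, cm = mm.loc[m, "chromosome"], mm.loc[m, "cM"]
            assert any(mm.loc[s, "chromosome"] == chrom
                       and abs(mm.loc[s, "cM"] - cm) <= 5.0
                       for s in res.selected), f"{m} not recovered"

    def test_self_absorption(self, small_panel):
        """Re-scanning a selected peak with itself as cofactor leaves no
        signal: its class indicators lie in the covariate span."""
        marker = small_panel.marker_ids[25]
        qtl = PlantedQTL(marker, "Rdw", main_effect=3.0)
        pheno = simulate_phenotypes(small_panel, [qtl], quiet_design(seed=2))
        rec = fit_marker_model(pheno, small_panel, marker,
                               cofactors=[marker], trait="Rdw")
        assert rec["p_M"] > 0.99

    def test_perfect_ld_pair_selects_exactly_one(self, small_panel):
        """Two markers with identical dosage: the scan must pick one and
        retire the other from the candidate pool."""
        j = small_panel.marker_index(small_panel.marker_ids[25])
        dosage = np.column_stack([small_panel.dosage,
                                  small_panel.dosage[:, j]])
        mm = pd.concat([
            small_panel.marker_map,
            pd.DataFrame({"marker": ["twin"],
                          "chromosome": [small_panel.marker_map["chromosome"][j]],
                          "cM": [small_panel.marker_map["cM"][j] + 0.01]}),
        ], ignore_index=True)
        panel = GenotypePanel(small_panel.genotype_ids, small_panel.subpops,
                              dosage, mm)
        orig = small_panel.marker_ids[25]
        qtl = PlantedQTL(orig, "Rdw", main_effect=3.0)
        pheno = simulate_phenotypes(panel, [qtl], quiet_design(seed=2))
        res = multilocus_scan(pheno, panel, "Rdw", MLMSpec(), threshold=4.0)
        pair = {orig, "twin"}
        assert len(pair & set(res.selected)) == 1

    def test_null_panel_rarely_selects(self, small_panel):
        pheno = simulate_phenotypes(small_panel, [],
                                    PhenoDesign(seed=99))
        thr = permutation_threshold(pheno, small_panel, "Rl", n_perm=100,
                                    seed=99)
        res = multilocus_scan(pheno, small_panel, "Rl", MLMSpec(), thr)
        assert len(res.selected) <= 1


def fake_scan(rows):
    df = pd.DataFrame(rows, columns=["marker", "chromosome", "cM", "p_M",
                                     "p_MxT"])
    df["LOD_M"] = -np.log10(df["p_M"])
    df["LOD_MxT"] = -np.log10(df["p_MxT"])
    return df


class TestMergeToQtl:
    def make_result(self, selected, rows, threshold=4.0):
        fs = fake_scan(rows)
        return MultilocusResult("Rdw", selected, fs,
                                [fs] * max(len(selected), 1), threshold)

    def test_lone_peak_collapses_to_point_interval(self):
        res = self.make_result(
            ["a"], [("a", "2H", 122.17, 1e-9, 0.5),
                    ("b", "2H", 140.0, 0.3, 0.4)])
        (rec,) = merge_to_qtl(res, None)
        assert rec.interval_cM == (122.17, 122.17)
        assert rec.effect_type == "M"

    def test_significant_flankers_widen_interval(self):
        res = self.make_result(
            ["p"], [("p", "5H", 95.0, 1e-12, 0.9),
                    ("f1", "5H", 94.44, 1e-6, 0.9),
                    ("f2", "5H", 99.93, 1e-5, 0.9),
                    ("far", "5H", 120.0, 1e-7, 0.9)])
        (rec,) = merge_to_qtl(res, None, flank_cM=5.0)
        assert rec.interval_cM == (94.44, 99.93)

    def test_distant_peaks_stay_separate(self):
        res = self.make_result(
            ["a", "b"], [("a", "3H", 10.0, 1e-8, 0.9),
                         ("b", "3H", 40.0, 1e-7, 0.9)])
        recs = merge_to_qtl(res, None)
        assert len(recs) == 2
        assert {r.qtl_name for r in recs} == {"QRdw.3H.a", "QRdw.3H.b"}

    def test_mxt_effect_type(self):
        res = self.make_result(["a"], [("a", "2H", 50.0, 0.3, 1e-8)])
        (rec,) = merge_to_qtl(res, None)
        assert rec.effect_type == "MxT"

    def test_both_tests_passing_is_m_mxt(self):
        res = self.make_result(["a"], [("a", "2H", 50.0, 1e-8, 1e-9)])
        (rec,) = merge_to_qtl(res, None)
        assert rec.effect_type == "M/MxT"

    def test_empty_selection_empty_result(self):
        res = self.make_result([], [("a", "1H", 0.0, 0.5, 0.5)])
        assert merge_to_qtl(res, None) == []


class TestCrossValidate:
    def test_strong_qtl_robustly_detected(self, small_panel):
        marker = small_panel.marker_ids[25]
        qtl = PlantedQTL(marker, "Rdw", main_effect=3.0)
        pheno = simulate_phenotypes(small_panel, [qtl], quiet_design(seed=17))
        cv = cross_validate(pheno, small_panel, "Rdw", MLMSpec(),
                            threshold=4.0, candidates=[marker],
                            n_runs=20, seed=17)
        row = cv.table.iloc[0]
        assert row["detection_rate"] >= 0.9
        assert row["passed"]

    def test_null_marker_not_detected(self, small_panel):
        pheno = simulate_phenotypes(small_panel, [], quiet_design(seed=18))
        cv = cross_validate(pheno, small_panel, "Rdw", MLMSpec(),
                            threshold=4.0,
                            candidates=[small_panel.marker_ids[3]],
                            n_runs=10, seed=18)
        assert cv.table["detection_rate"].iloc[0] <= 0.1

    def test_leave_zero_reproduces_full_scan(self, small_panel):
        marker = small_panel.marker_ids[25]
        qtl = PlantedQTL(marker, "Rdw", main_effect=3.0)
        pheno = simulate_phenotypes(small_panel, [qtl], quiet_design(seed=19))
        full = multilocus_scan(pheno, small_panel, "Rdw", MLMSpec(), 4.0)
        cv = cross_validate(pheno, small_panel, "Rdw", MLMSpec(), 4.0,
                            candidates=full.selected, leave_frac=0.0,
                            n_runs=3, seed=0)
        assert (cv.table["detection_rate"] == 1.0).all()
        fs = full.first_scan.set_index("marker")
        for _, row in cv.table.iterrows():
            expect = float(min(fs.loc[row["marker"], "p_M"],
                               fs.loc[row["marker"], "p_MxT"]))
            assert row["mean_p"] == pytest.approx(expect)


class TestVarianceExplained:
    def test_marker_explaining_everything(self):
        dosage = np.array([[0.0], [0.0], [2.0], [2.0]])
        mm = pd.DataFrame({"marker": ["m"], "chromosome": ["1H"], "cM": [0.0]})
        panel = GenotypePanel(["a", "b", "c", "d"], ["unknown"] * 4, dosage,
                              mm)
        rows = [(g, "control", 2014, 1, "Rdw", 1.0 if g in ("a", "b") else 9.0)
                for g in ("a", "b", "c", "d")]
        pheno = pd.DataFrame(rows, columns=["genotype", "treatment", "year",
                                            "replicate", "trait", "value"])
        assert variance_explained(pheno, panel, "Rdw", "m") == pytest.approx(100.0)

    def test_independent_marker_near_zero(self, small_panel):
        pheno = simulate_phenotypes(small_panel, [], quiet_design(seed=23))
        v = variance_explained(pheno, small_panel, "Rdw",
                               small_panel.marker_ids[7])
        assert v < 10.0

    def test_constructed_half_variance(self):
        """Orthogonal two-marker design where the tested marker accounts
        for half the line-mean variance."""
        dosage = np.array([[0, 0], [0, 2], [2, 0], [2, 2]], dtype=float)
        mm = pd.DataFrame({"marker": ["m1", "m2"], "chromosome": "1H",
                           "cM": [0.0, 50.0]})
        panel = GenotypePanel(list("abcd"), ["unknown"] * 4, dosage, mm)
        vals = {"a": 0.0, "b": 1.0, "c": 1.0, "d": 2.0}  # additive, equal
        rows = [(g, "control", 2014, 1, "Rdw", v) for g, v in vals.items()]
        pheno = pd.DataFrame(rows, columns=["genotype", "treatment", "year",
                                            "replicate", "trait", "value"])
        assert variance_explained(pheno, panel, "Rdw", "m1") == pytest.approx(
            50.0, abs=5.0)
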