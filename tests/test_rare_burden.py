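"""Qualification rule, carrier counting, one-tailed Fisher burden test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln

import varscreen as vs
from varscreen.containers import PREDICTOR_FIELDS


def fisher_tail_brute(k_case, n_cases, k_ctrl, n_controls):
    """log-space summation of hypergeometric masses for P(X >= k_case),
    X ~ Hypergeom(N = n_cases + n_controls, K = k_case + k_ctrl, n = n_cases)."""
    N, K, n = n_cases + n_controls, k_case + k_ctrl, n_cases

    def logpmf(x):
        return (gammaln(K + 1) - gammaln(x + 1) - gammaln(K - x + 1)
                + gammaln(N - K + 1) - gammaln(n - x + 1) - gammaln(N - K - n + x + 1)
                + gammaln(n + 1) + gammaln(N - n + 1) - gammaln(N + 1))

    xs = np.arange(k_case, min(K, n) + 1)
    xs = xs[(n - xs) <= (N - K)]
    if xs.size == 0:
        return 0.0
    lp = logpmf(xs)
    m = lp.max()
    return float(np.exp(m) * np.exp(lp - m).sum())


def make_exome(rows, genotypes, n_cases):
    base = {f: "T" for f in PREDICTOR_FIELDS}
    recs = []
    for i, row in enumerate(rows):
        rec = {"variant_id": f"v{i}", "gene": row.get("gene", "G1"),
               "chrom": "1", "pos": 100 + i, "ref": "C", "alt": "T",
               "af_nfe": row.get("af", 0.0005), **base,
               "clinvar": row.get("clinvar", ""), "intervar": row.get("intervar", ""),
               "hgmd": row.get("hgmd", "")}
        rec.update(row.get("calls", {}))
        recs.append(rec)
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n = genotypes.shape[0]
    is_case = np.arange(n) < n_cases
    return vs.ExomeCohort([f"s{i}" for i in range(n)], is_case, genotypes,
                          pd.DataFrame(recs))


class TestQualify:
    def test_common_variant_excluded_despite_damaging_calls(self):
        ex = make_exome([{"af": 0.002, "calls": {"SIFT_pred": "D"}}],
                        np.zeros((4, 1)), 2)
        q, rep = vs.qualify_variants(ex)
        assert len(q.variants) == 0
        assert rep["reason"].iloc[0] == "maf_above_max"

    def test_maf_boundary_inclusive(self):
        ex = make_exome([{"af": 0.001, "calls": {"SIFT_pred": "D"}}],
                        np.zeros((4, 1)), 2)
        q, _ = vs.qualify_variants(ex)
        assert len(q.variants) == 1

    def test_single_damaging_call_suffices(self):
        ex = make_exome([{"af": 0.0005, "calls": {"SIFT_pred": "D"}}],
                        np.zeros((4, 1)), 2)
        q, _ = vs.qualify_variants(ex)
        assert len(q.variants) == 1

    def test_all_benign_calls_fail(self):
        ex = make_exome([{"af": 0.0005}], np.zeros((4, 1)), 2)
        q, rep = vs.qualify_variants(ex)
        assert len(q.variants) == 0
        assert rep["reason"].iloc[0] == "no_damaging_call"

    @pytest.mark.parametrize("column,value", list(vs.DEFAULT_PREDICATES))
    def test_every_predicate_qualifies_alone(self, column, value):
        ex = make_exome([{"af": 0.0005, "calls": {column: value}}],
                        np.zeros((4, 1)), 2)
        q, _ = vs.qualify_variants(ex)
        assert len(q.variants) == 1

    def test_unknown_call_letters_never_qualify(self):
        ex = make_exome([{"af": 0.0005, "calls": {"SIFT_pred": "X"}}],
                        np.zeros((4, 1)), 2)
        q, _ = vs.qualify_variants(ex)
        assert len(q.variants) == 0

    def test_monotone_in_maf_ceiling(self, exome_cohort):
        tight, _ = vs.qualify_variants(exome_cohort,
                                       vs.QualifyingRule(maf_max=0.0005))
        loose, _ = vs.qualify_variants(exome_cohort,
                                       vs.QualifyingRule(maf_max=0.001))
        assert set(tight.variants.variant_id) <= set(loose.variants.variant_id)


class TestCountCarriers:
    def test_two_hets_one_gene_is_compound_het(self):
        g = [[1, 1], [0, 0], [0, 0]]
        ex = make_exome([{"calls": {"SIFT_pred": "D"}},
                         {"calls": {"SIFT_pred": "D"}}], g, 1)
        q, _ = vs.qualify_variants(ex)
        t = vs.count_carriers(q)
        row = t.counts.loc["G1"]
        assert row.case_het == 1 and row.case_ch == 1 and row.case_hom == 0
        assert t.dominant_carriers("case")["G1"] == 1
        assert t.recessive_carriers("case")["G1"] == 1

    def test_single_het_not_recessive(self):
        g = [[1, 0], [0, 0]]
        ex = make_exome([{"calls": {"SIFT_pred": "D"}},
                         {"calls": {"SIFT_pred": "D"}}], g, 1)
        t = vs.count_carriers(vs.qualify_variants(ex)[0])
        row = t.counts.loc["G1"]
        assert row.case_het == 1 and row.case_ch == 0
        assert t.recessive_carriers("case")["G1"] == 0

    def test_homozygote_dominant_and_recessive(self):
        g = [[2, 0], [0, 0]]
        ex = make_exome([{"calls": {"SIFT_pred": "D"}},
                         {"calls": {"SIFT_pred": "D"}}], g, 1)
        t = vs.count_carriers(vs.qualify_variants(ex)[0])
        row = t.counts.loc["G1"]
        assert row.case_hom == 1 and row.case_het == 0
        assert t.dominant_carriers("case")["G1"] == 1
        assert t.recessive_carriers("case")["G1"] == 1

    def test_missing_genotype_not_carried(self):
        g = [[vs.MISSING, 0], [0, 0]]
        ex = make_exome([{"calls": {"SIFT_pred": "D"}},
                         {"calls": {"SIFT_pred": "D"}}], g, 1)
        t = vs.count_carriers(vs.qualify_variants(ex)[0])
        assert t.dominant_carriers("case")["G1"] == 0


class TestFisherBurden:
    def _table(self, case_het, ctrl_het, n_cases=87, n_controls=2719):
        counts = pd.DataFrame({"case_het": [case_het], "case_ch": [0],
                               "case_hom": [0], "ctrl_het": [ctrl_het],
                               "ctrl_ch": [0], "ctrl_hom": [0]}, index=["G"])
        return vs.CarrierTable(counts, n_cases, n_controls)

    def test_reported_counts_4_vs_0(self):
        res = vs.fisher_burden(self._table(4, 0))
        assert res.loc["G", "p_value"] == pytest.approx(8.64e-7, rel=5e-3)

    def test_reported_counts_24_vs_51(self):
        res = vs.fisher_burden(self._table(24, 51))
        assert res.loc["G", "p_value"] == pytest.approx(1.72e-19, rel=5e-3)

    def test_zero_case_carriers_p_one(self):
        res = vs.fisher_burden(self._table(0, 30))
        assert res.loc["G", "p_value"] == 1.0

    def test_zero_total_carriers_untestable(self):
        res = vs.fisher_burden(self._table(0, 0))
        assert res.loc["G", "p_value"] == 1.0
        assert bool(res.loc["G", "untestable"])

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.data())
    def test_property_matches_brute_force(self, data):
        n_cases = data.draw(st.integers(1, 300))
        n_controls = data.draw(st.integers(1, 5000))
        k_case = data.draw(st.integers(0, min(n_cases, 40)))
        k_ctrl = data.draw(st.integers(0, min(n_controls, 80)))
        res = vs.fisher_burden(self._table(k_case, k_ctrl, n_cases, n_controls))
        brute = fisher_tail_brute(k_case, n_cases, k_ctrl, n_controls) \
            if k_case > 0 else 1.0
        assert res.loc["G", "p_value"] == pytest.approx(min(brute, 1.0),
                                                        rel=1e-7, abs=1e-12)


class TestReportedTable:
    def test_all_55_reported_rows_reproduced(self):
        """Every published P_DOM follows from its printed carrier counts."""
        table = vs.load_reported_burden_counts()
        counts = table.rename(columns={
            "CASE_COUNT_HET": "case_het", "CASE_COUNT_CH": "case_ch",
            "CASE_COUNT_HOM": "case_hom", "CONTROL_COUNT_HET": "ctrl_het",
            "CONTROL_COUNT_CH": "ctrl_ch", "CONTROL_COUNT_HOM": "ctrl_hom",
        }).set_index("GENE")
        ct = vs.CarrierTable(counts[list(vs.CarrierTable.COUNT_COLUMNS)], 87, 2719)
        res = vs.fisher_burden(ct, "dominant")
        for gene, printed in zip(counts.index, counts["P_DOM"]):
            assert res.loc[gene, "p_value"] == pytest.approx(printed, rel=5e-3), gene
        assert len(res) == 55
        assert res["significant"].all()  # all below 0.05 / 21,306


class TestSummaryControlMode:
    def _case_table(self, k_case, n_cases=87):
        counts = pd.DataFrame({"case_het": [k_case], "case_ch": [0],
                               "case_hom": [0], "ctrl_het": [0],
                               "ctrl_ch": [0], "ctrl_hom": [0]}, index=["G1"])
        return vs.CarrierTable(counts, n_cases, 0)

    def _qualifying(self):
        ex = make_exome([{"calls": {"SIFT_pred": "D"}}], np.zeros((87, 1)), 87)
        return vs.qualify_variants(ex)[0]

    def test_ac_an_mapped_to_carriers(self):
        q = self._qualifying()
        res = vs.summary_control_burden(
            q, self._case_table(4),
            control_ac=pd.Series({"v0": 2}), control_an=pd.Series({"v0": 5438}))
        assert res.loc["G1", "ctrl_carriers"] == 2
        assert res.loc["G1", "n_controls"] == 2719

    def test_equivalent_to_internal_mode_at_same_counts(self):
        q = self._qualifying()
        res = vs.summary_control_burden(
            q, self._case_table(4),
            control_ac=pd.Series({"v0": 0}), control_an=pd.Series({"v0": 5438}))
        internal = fisher_tail_brute(4, 87, 0, 2719)
        assert res.loc["G1", "p_value"] == pytest.approx(internal, rel=1e-6)

    def test_allele_count_capped_at_cohort_size(self):
        q = self._qualifying()
        res = vs.summary_control_burden(
            q, self._case_table(4),
            control_ac=pd.Series({"v0": 10_000}), control_an=pd.Series({"v0": 5438}))
        assert res.loc["G1", "ctrl_carriers"] == 2719
        assert bool(res.loc["G1", "capped"])


class TestCoverageNormalize:
    def _table(self, frac_case, frac_ctrl):
        counts = pd.DataFrame({
            "case_het": [5], "case_ch": [0], "case_hom": [0],
            "ctrl_het": [10], "ctrl_ch": [0], "ctrl_hom": [0],
            "callable_frac_case": [frac_case], "callable_frac_ctrl": [frac_ctrl],
        }, index=["G"])
        return vs.CarrierTable(counts, 87, 2719)

    def test_equal_fractions_identity(self):
        out = vs.coverage_normalize(self._table(0.9, 0.9))
        assert out.counts.loc["G", "eff_n_controls"] == 2719

    def test_half_coverage_halves_effective_controls(self):
        out = vs.coverage_normalize(self._table(1.0, 0.5))
        assert out.counts.loc["G", "eff_n_controls"] == round(2719 * 0.5)

    def test_case_counts_never_change(self):
        out = vs.coverage_normalize(self._table(0.8, 0.4))
        assert out.counts.loc["G", "case_het"] == 5
        assert out.n_cases == 87

    def test_zero_fraction_errors(self):
        with pytest.raises(ValueError):
            vs.coverage_normalize(self._table(0.0, 0.5))


class TestBonferroni:
    def test_genome_wide_threshold(self):
        assert vs.bonferroni_threshold(21_306, 0.05) == pytest.approx(2.347e-6,
                                                                      rel=5e-4)

    def test_single_gene_identity(self):
        assert vs.bonferroni_threshold(1, 0.03) == 0.03

    def test_direct_arithmetic(self):
        assert vs.bonferroni_threshold(10, 0.05) == pytest.approx(0.005)


class TestNullCalibration:
    def test_null_midp_uniform(self):
        """With equal carrier rates the mid-P corrected burden P-values are
        uniform (the raw one-tailed Fisher is conservative by discreteness)."""
        from scipy.stats import hypergeom, kstest
        cfg = vs.SimConfig(seed=213, exome_genes=1000, wes_cases=500,
                           wes_controls=500, carrier_rate_cases=0.2,
                           carrier_rate_controls=0.2)
        ex = vs.simulate_exome_cohort(cfg)
        t = vs.count_carriers(vs.qualify_variants(ex)[0])
        res = vs.fisher_burden(t, "dominant")
        kc = res["case_carriers"].to_numpy()
        kt = res["ctrl_carriers"].to_numpy()
        pmid = res["p_value"].to_numpy() - 0.5 * hypergeom.pmf(
            kc, 1000, kc + kt, 500)
        assert kstest(pmid, "uniform").pvalue > 0.01

    def test_equal_carrier_rates_conservative(self):
        cfg = vs.SimConfig(seed=71, exome_genes=300, wes_cases=80,
                           wes_controls=400, carrier_rate_cases=0.05,
                           carrier_rate_controls=0.05)
        ex = vs.simulate_exome_cohort(cfg)
        t = vs.count_carriers(vs.qualify_variants(ex)[0])
        res = vs.fisher_burden(t, "dominant", threshold=0.05)
        frac = res["significant"].mean()
        # discreteness makes the one-tailed Fisher conservative
        assert frac <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 300)
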