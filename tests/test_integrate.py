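import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.meta_analysis import combine_effects

import twindiff as td
from twindiff.errors import AnalysisError
from twindiff.types import SignificanceResult


def _sig(study_id, genes, n_tested=10, tau=1.0):
    return SignificanceResult(study_id=study_id, threshold_95=tau,
                              significant_genes=frozenset(genes), n_tested=n_tested)


def _genes(study_id, symbols, diffs):
    return pd.DataFrame({"gene": symbols, "study_id": study_id,
                         "mean_diff": diffs, "se": 1.0})


class TestOverlap:
    def test_half_overlap(self):
        res = {"A": _sig("A", {"g1", "g2"}), "B": _sig("B", {"g1", "g2"})}
        uni = {"A": frozenset(f"g{i}" for i in range(1, 5)),
               "B": frozenset(f"g{i}" for i in range(1, 5))}
        table = td.overlap_table(res, uni).set_index(["phenotype_a", "phenotype_b"])
        assert table.loc[("A", "B"), "overlap_pct"] == 50.0
        assert table.loc[("A", "B"), "n_measured_both"] == 4

    def test_disjoint_and_self_pair(self):
        res = {"A": _sig("A", {f"s{i}" for i in range(20)}),
               "B": _sig("B", {"other"})}
        uni = {"A": frozenset(f"g{i}" for i in range(980)) | frozenset(f"s{i}" for i in range(20)),
               "B": frozenset(f"g{i}" for i in range(980)) | {"other"}}
        table = td.overlap_table(res, uni).set_index(["phenotype_a", "phenotype_b"])
        assert table.loc[("A", "B"), "overlap_pct"] == 0.0
        # self-pair: 20 significant of 1000 measured = 2.00%
        assert table.loc[("A", "A"), "overlap_pct"] == 2.00

    def test_empty_measured_intersection_is_missing(self):
        res = {"A": _sig("A", set()), "B": _sig("B", set())}
        uni = {"A": frozenset({"g1"}), "B": frozenset({"g2"})}
        table = td.overlap_table(res, uni).set_index(["phenotype_a", "phenotype_b"])
        assert pd.isna(table.loc[("A", "B"), "overlap_pct"])
        with pytest.raises(AnalysisError):
            td.overlap_table({"A": res["A"]}, uni)


class TestSpearman:
    def test_identical_and_reversed(self):
        a = _genes("A", list("wxyz"), [1.0, 2.0, 3.0, 4.0])
        rho, p, n = td.diff_correlation(a, a)
        assert rho == 1.0 and n == 4
        b = _genes("B", list("wxyz"), [4.0, 3.0, 2.0, 1.0])
        rho, _, _ = td.diff_correlation(a, b)
        assert rho == -1.0

    def test_tied_ranks_hand_value(self):
        a = _genes("A", list("wxyz"), [1.0, 2.0, 3.0, 4.0])
        b = _genes("B", list("wxyz"), [1.0, 2.0, 2.0, 4.0])
        rho, p, _ = td.diff_correlation(a, b)
        # average ranks for the tie in b: (1, 2.5, 2.5, 4) -> 3/sqrt(10)
        assert rho == pytest.approx(3 / np.sqrt(10), rel=1e-12)

    def test_restricted_to_shared_genes_and_min_n(self):
        a = _genes("A", ["g1", "g2", "g3", "only_a"], [1, 2, 3, 9])
        b = _genes("B", ["g1", "g2", "g3", "only_b"], [2, 4, 6, -9])
        rho, _, n = td.diff_correlation(a, b)
        assert n == 3 and rho == 1.0
        with pytest.raises(AnalysisError, match="co-measured"):
            td.diff_correlation(a.iloc[:2], b)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.integers(-100, 100), min_size=4, max_size=30, unique=True))
    def test_monotone_transform_gives_rho_one(self, vals):
        symbols = [f"g{i}" for i in range(len(vals))]
        a = _genes("A", symbols, [float(v) for v in vals])
        b = _genes("B", symbols, np.exp(np.asarray(vals, dtype=float) / 100.0))
        rho, _, _ = td.diff_correlation(a, b)
        assert rho == pytest.approx(1.0, abs=1e-12)


class TestDLMeta:
    def test_single_study_conventions(self):
        r = td.dl_meta([(2.5, 0.7)])
        assert r["re_estimate"] == pytest.approx(2.5, rel=1e-12)
        assert r["re_se"] == pytest.approx(0.7, rel=1e-12)
        assert r["tau2"] == 0 and r["I2"] == 0 and r["QEp"] == 1.0 and r["Q"] == 0.0

    def test_homogeneous_studies(self):
        r = td.dl_meta([(2.0, 1.0)] * 3)
        assert r["Q"] == pytest.approx(0.0, abs=1e-12)
        assert r["tau2"] == 0 and r["I2"] == 0
        assert r["re_estimate"] == pytest.approx(2.0, rel=1e-12)
        assert r["re_se"] == pytest.approx(1 / np.sqrt(3), rel=1e-12)

    def test_hand_computed_two_study_case(self):
        # FE mean 1, Q = 2, DL tau2 = 1, I2 = 50%, RE weights equal
        r = td.dl_meta([(0.0, 1.0), (2.0, 1.0)])
        assert r["Q"] == pytest.approx(2.0, rel=1e-12)
        assert r["tau2"] == pytest.approx(1.0, rel=1e-12)
        assert r["I2"] == pytest.approx(50.0, rel=1e-12)
        assert r["re_estimate"] == pytest.approx(1.0, rel=1e-12)
        assert r["re_se"] == pytest.approx(1.0, rel=1e-12)
        assert r["QEp"] == pytest.approx(stats.chi2.sf(2, 1), rel=1e-12)

    def test_rejects_bad_input(self):
        with pytest.raises(AnalysisError):
            td.dl_meta([])
        with pytest.raises(AnalysisError):
            td.dl_meta([(1.0, -1.0)])

    def test_matches_statsmodels_dl(self):
        """Cross-check against statsmodels' DL moment estimator.

        statsmodels reports the untruncated moment estimate, so the canonical
        tau2 = max(0, .) must match its value clipped at zero; the pooled
        estimate is compared where no truncation occurred (the truncated case
        reduces to the fixed-effect pool, checked separately)."""
        rng = np.random.default_rng(12)
        compared = 0
        for _ in range(25):
            k = int(rng.integers(2, 9))
            m = rng.normal(0, 3, k)
            se = 10 ** rng.uniform(-0.5, 0.5, k)
            r = td.dl_meta(list(zip(m, se)))
            res = combine_effects(m, se ** 2, method_re="dl")
            assert r["tau2"] == pytest.approx(max(0.0, res.tau2), rel=1e-9, abs=1e-12)
            assert r["Q"] == pytest.approx(res.q, rel=1e-9)
            if res.tau2 > 0:
                frame = res.summary_frame()
                assert r["re_estimate"] == pytest.approx(
                    frame.loc["random effect", "eff"], rel=1e-9)
                assert r["re_se"] == pytest.approx(
                    frame.loc["random effect", "sd_eff"], rel=1e-9)
                compared += 1
        assert compared >= 10

    # Independent reference values from metafor's rma.uni(method="DL"),
    # frozen; covers truncated and non-truncated tau2.
    @pytest.mark.parametrize("m, se, expect", [
        ((0, 2), (1, 1),
         dict(re_estimate=1.0, re_se=1.0, tau2=1.0, Q=2.0,
              QEp=0.15729920705, I2=50.0, p_value=0.317310507863)),
        ((1.2, -0.5, 3.3), (0.4, 1.1, 0.9),
         dict(re_estimate=1.39740113266, re_se=0.88259292134, tau2=1.6928440367,
              Q=7.66316274074, QEp=0.0216753118177, I2=73.9011154054,
              p_value=0.113355229802)),
        ((10, 12, 8, 15, 11), (2, 3, 1.5, 4, 2.5),
         dict(re_estimate=9.81113212645, re_se=0.986260654369, tau2=0.0,
              Q=3.90805037678, QEp=0.418592880315, I2=0.0)),
        ((-1.5, 0.2, 0.1, -0.3), (0.2, 0.5, 0.3, 0.4),
         dict(re_estimate=-0.415841017349, re_se=0.48703201041,
              tau2=0.820185758514, Q=26.8094667466, QEp=6.45445390216e-06,
              I2=88.8099228964, p_value=0.39320092369)),
        ((5, 5.1), (0.1, 0.2),
         dict(re_estimate=5.02, re_se=0.0894427191, tau2=0.0, Q=0.2,
              QEp=0.654720846019, I2=0.0)),
    ])
    def test_matches_metafor_reference(self, m, se, expect):
        r = td.dl_meta(list(zip(m, se)))
        for key, val in expect.items():
            assert r[key] == pytest.approx(val, rel=1e-9, abs=1e-11), key

    def test_homogeneity_reduces_to_fixed_effect(self):
        """Whenever tau2 truncates to 0, DL equals the FE pooled estimate."""
        rng = np.random.default_rng(5)
        found = 0
        for _ in range(50):
            k = int(rng.integers(2, 6))
            m = rng.normal(0, 0.1, k)
            se = np.full(k, 2.0)
            r = td.dl_meta(list(zip(m, se)))
            if r["tau2"] == 0:
                fe_m, fe_se, _, _ = td.fixed_effect_pool(list(zip(m, se)))
                assert r["re_estimate"] == pytest.approx(fe_m, rel=1e-12)
                assert r["re_se"] == pytest.approx(fe_se, rel=1e-12)
                found += 1
        assert found > 10

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.lists(st.tuples(st.floats(-20, 20), st.floats(0.05, 5)),
                    min_size=1, max_size=8))
    def test_invariants_and_permutation(self, estimates):
        r = td.dl_meta(estimates)
        assert 0 <= r["I2"] <= 100 and r["tau2"] >= 0 and r["Q"] >= 0
        assert 0 <= r["QEp"] <= 1
        r2 = td.dl_meta(estimates[::-1])
        assert r2["Q"] == pytest.approx(r["Q"], rel=1e-9, abs=1e-9)
        assert r2["re_estimate"] == pytest.approx(r["re_estimate"], rel=1e-9, abs=1e-9)


class TestMetaTable:
    def test_vectorized_table_matches_per_gene_dl(self):
        rng = np.random.default_rng(6)
        tables = {}
        for sid in "ABCD":
            n = int(rng.integers(15, 30))
            genes = rng.choice([f"g{i}" for i in range(40)], size=n, replace=False)
            tables[sid] = _genes(sid, list(genes), rng.normal(0, 2, n))
            tables[sid]["se"] = 10 ** rng.uniform(-0.5, 0.5, n)
        meta = td.meta_analyze_genes(tables).set_index("gene")
        long = pd.concat(tables.values())
        for gene, grp in long.groupby("gene"):
            ref = td.dl_meta(list(zip(grp["mean_diff"], grp["se"])))
            row = meta.loc[gene]
            assert row["k"] == len(grp)
            for key in ("re_estimate", "re_se", "tau2", "Q", "QEp", "I2", "p_value"):
                assert row[key] == pytest.approx(ref[key], rel=1e-8, abs=1e-10), (gene, key)
        # FDR columns filled over all genes
        np.testing.assert_allclose(meta["q_value"],
                                   td.bh_fdr(meta["p_value"]), rtol=1e-12)
        np.testing.assert_allclose(meta["QEp_fdr"],
                                   td.bh_fdr(meta["QEp"]), rtol=1e-12)

    def test_parameter_recovery_tau2(self):
        """500 replicate genes with true tau2 = 1, k = 7, se ~= 1: the mean DL
        tau2-hat lands within 15% of the truth."""
        rng = np.random.default_rng(99)
        k, n_genes = 7, 500
        tau2_hats = np.empty(n_genes)
        for g in range(n_genes):
            theta = rng.normal(0.0, 1.0, k)           # between-study spread, tau2=1
            m = theta + rng.normal(0.0, 1.0, k)       # within-study error, se=1
            tau2_hats[g] = td.dl_meta([(mi, 1.0) for mi in m])["tau2"]
        assert abs(tau2_hats.mean() - 1.0) < 0.15

    def test_null_heterogeneity_i2_spike_at_zero(self):
        """With no true heterogeneity the I2 estimator piles up at exactly 0."""
        rng = np.random.default_rng(100)
        i2 = np.empty(400)
        for g in range(400):
            m = rng.normal(0.0, 1.0, 7)
            i2[g] = td.dl_meta([(mi, 1.0) for mi in m])["I2"]
        assert np.median(i2) == 0.0
        assert (i2 == 0).mean() > 0.3


class TestOverallSelection:
    def _meta(self, rows):
        df = pd.DataFrame(rows)
        df["q_value"] = td.bh_fdr(df["p_value"])
        df["QEp_fdr"] = td.bh_fdr(df["QEp"])
        return df

    def test_k1_gene_excluded_despite_tiny_p(self):
        rows = [dict(gene="solo", k=1, re_estimate=50.0, p_value=1e-12, QEp=1.0)]
        rows += [dict(gene=f"g{i}", k=3, re_estimate=0.01 * i, p_value=0.9, QEp=0.5)
                 for i in range(40)]
        sel, het, tau95 = td.overall_selection(self._meta(rows))
        assert "solo" not in sel and sel == frozenset()

    def test_spike_gene_selected(self):
        rows = [dict(gene="spike", k=7, re_estimate=10.0, p_value=1e-10, QEp=0.9)]
        rows += [dict(gene=f"g{i}", k=4, re_estimate=0.001 * (i + 1), p_value=0.5,
                      QEp=0.6) for i in range(60)]
        sel, het, tau95 = td.overall_selection(self._meta(rows))
        assert sel == frozenset({"spike"}) and het == frozenset()

    def test_heterogeneous_set_from_qep_fdr(self):
        rows = [dict(gene=f"h{i}", k=5, re_estimate=0.0, p_value=0.9, QEp=1e-8)
                for i in range(3)]
        rows += [dict(gene=f"g{i}", k=5, re_estimate=0.0, p_value=0.9, QEp=0.7)
                 for i in range(30)]
        _, het, _ = td.overall_selection(self._meta(rows))
        assert het == frozenset({"h0", "h1", "h2"})
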