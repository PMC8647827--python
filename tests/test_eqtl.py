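import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sveqtl.eqtl import (
    EqtlResult,
    AssociationStat,
    MonomorphicError,
    VariantMatrix,
    beta_empirical_p,
    best_tag_r2,
    classify_leads,
    compare_egene_counts,
    count_egenes_per_evariant,
    fit_beta_null,
    gene_level_fdr,
    lead_enrichment,
    map_cis_gene,
    nominal_association,
    residualize,
)
from sveqtl.genio import ExpressionPanel, GeneModel, VariantRecord
from sveqtl.intervals import GenomicInterval


def _panel(values, genes=None, samples=None, tissue="t1"):
    values = np.atleast_2d(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionPanel(tissue, pd.DataFrame(values, index=genes, columns=samples))


class TestResidualize:
    def test_intercept_only_centers(self, rng):
        panel = _panel(rng.normal(size=(3, 10)))
        cov = pd.DataFrame(index=panel.sample_ids)
        out = residualize(panel, cov)
        np.testing.assert_allclose(out.values.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(
            out.values.to_numpy(),
            panel.values.to_numpy() - panel.values.to_numpy().mean(1, keepdims=True),
            atol=1e-10,
        )

    def test_perfect_fit_gives_zero_residuals(self, rng):
        c = rng.normal(size=10)
        cov = pd.DataFrame({"c": c}, index=[f"s{i}" for i in range(10)])
        panel = _panel(3.0 + 2.0 * c)
        out = residualize(panel, cov)
        np.testing.assert_allclose(out.values.to_numpy(), 0, atol=1e-10)

    def test_residuals_orthogonal_to_covariates(self, rng):
        cov = pd.DataFrame(rng.normal(size=(30, 3)), index=[f"s{i}" for i in range(30)],
                           columns=list("abc"))
        panel = _panel(rng.normal(size=(5, 30)))
        out = residualize(panel, cov)
        dots = out.values.to_numpy() @ cov.to_numpy()
        assert np.abs(dots).max() < 1e-8

    def test_collinear_covariates_dropped_with_warning(self, rng):
        c = rng.normal(size=12)
        cov = pd.DataFrame({"a": c, "b": 2 * c}, index=[f"s{i}" for i in range(12)])
        panel = _panel(rng.normal(size=(2, 12)))
        with pytest.warns(UserWarning, match="collinear"):
            residualize(panel, cov)


class TestNominalAssociation:
    def test_exact_linear_fit(self):
        x = np.arange(10.0)
        st = nominal_association(x, 2 * x)
        assert st.slope == pytest.approx(2.0)
        assert st.nominal_p < 1e-12

    def test_textbook_five_points(self):
        # x=(0..4), y=(1,2,1,3,5): closed-form least squares slope 0.9
        st = nominal_association(np.arange(5.0), np.array([1, 2, 1, 3, 5.0]))
        assert st.slope == pytest.approx(0.9)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(1)
        ps = []
        x = rng.normal(size=1000)
        for _ in range(300):
            ps.append(nominal_association(x, rng.normal(size=1000)).nominal_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_monomorphic_raises(self):
        with pytest.raises(MonomorphicError):
            nominal_association(np.ones(10), np.arange(10.0))

    def test_missing_dosage_dropped_pairwise(self):
        x = np.array([0, 1, 2, np.nan, 1, 0, 2, 1.0])
        y = 3 * x + 1
        y[3] = 99.0
        st = nominal_association(x, y)
        assert st.n == 7
        assert st.slope == pytest.approx(3.0)


class TestBetaNull:
    def test_uniform_nulls_recover_unit_shapes(self, rng):
        a, b = fit_beta_null(rng.uniform(size=10_000))
        assert a == pytest.approx(1.0, abs=0.05)
        assert b == pytest.approx(1.0, abs=0.05)

    def test_parameter_recovery_within_ten_percent(self, rng):
        a, b = fit_beta_null(rng.beta(0.8, 40, size=10_000))
        assert abs(a - 0.8) / 0.8 < 0.10
        assert abs(b - 40) / 40 < 0.10

    def test_monotone_and_small_at_null_minimum(self, rng):
        nulls = rng.beta(1, 30, size=1_000)
        a, b = fit_beta_null(nulls)
        lo = beta_empirical_p(nulls.min(), a, b)
        assert lo < 0.01
        grid = np.linspace(nulls.min(), nulls.max(), 20)
        vals = [beta_empirical_p(g, a, b) for g in grid]
        assert np.all(np.diff(vals) >= 0)

    def test_degenerate_and_undersized_nulls_rejected(self):
        with pytest.raises(ValueError):
            fit_beta_null(np.full(100, 0.25))
        with pytest.raises(ValueError):
            fit_beta_null(np.linspace(0.1, 0.9, 10))


def _make_variant(vid, vclass, chrom, start, end, dosages):
    return VariantRecord(vid, vclass, chrom, start, end, np.asarray(dosages, float))


class TestMapCisGene:
    def _setup(self, rng, slope=0.0, n=100):
        gene = GeneModel("g0", "chr1", 500_000, 520_000, "+",
                         exons=[GenomicInterval("chr1", 500_000, 500_200)])
        dos = rng.binomial(2, 0.3, size=(8, n)).astype(float)
        variants = [
            _make_variant(f"SNV_{i:05d}", "SNV", "chr1", 400_000 + 30_000 * i,
                          400_001 + 30_000 * i, dos[i])
            for i in range(8)
        ]
        y = rng.normal(size=n) + slope * dos[3]
        panel = _panel(y, genes=["g0"], samples=[f"s{i}" for i in range(n)])
        vm = VariantMatrix(variants, n)
        return gene, vm, panel

    def test_planted_effect_detected(self, rng):
        gene, vm, panel = self._setup(rng, slope=1.5)
        res = map_cis_gene(gene, vm, panel, n_perm=200, seed=1)
        assert res.lead.variant_id == "SNV_00003"
        assert res.empirical_p < 0.01

    def test_null_empirical_p_uniform_over_replicates(self):
        ps = []
        for seed in range(60):
            rng = np.random.default_rng(1_000 + seed)
            gene, vm, panel = self._setup(rng, slope=0.0)
            ps.append(map_cis_gene(gene, vm, panel, n_perm=150, seed=seed).empirical_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_perfect_ld_tie_broken_deterministically(self, rng):
        gene = GeneModel("g0", "chr1", 500_000, 520_000, "+")
        dos = rng.binomial(2, 0.4, size=50).astype(float)
        va = _make_variant("SNV_00001", "SNV", "chr1", 480_000, 480_001, dos)
        vb = _make_variant("SNV_00002", "SNV", "chr1", 470_000, 470_001, dos)
        y = dos * 0.8 + rng.normal(size=50)
        panel = _panel(y, genes=["g0"], samples=[f"s{i}" for i in range(50)])
        res_ab = map_cis_gene(gene, VariantMatrix([va, vb], 50), panel, n_perm=100, seed=0)
        res_ba = map_cis_gene(gene, VariantMatrix([vb, va], 50), panel, n_perm=100, seed=0)
        # leftmost position wins either way, empirical p unchanged
        assert res_ab.lead.variant_id == "SNV_00002" == res_ba.lead.variant_id
        assert res_ab.empirical_p == pytest.approx(res_ba.empirical_p)

    def test_empty_cis_set_returns_none(self, rng):
        gene = GeneModel("g9", "chr2", 500_000, 520_000, "+")
        _, vm, panel = self._setup(rng)
        panel = _panel(panel.values.to_numpy(), genes=["g9"],
                       samples=panel.sample_ids)
        assert map_cis_gene(gene, vm, panel, n_perm=100, seed=0) is None

    def test_deterministic_under_seed(self, rng):
        gene, vm, panel = self._setup(rng, slope=0.5)
        r1 = map_cis_gene(gene, vm, panel, n_perm=200, seed=42)
        r2 = map_cis_gene(gene, vm, panel, n_perm=200, seed=42)
        assert r1.empirical_p == r2.empirical_p
        assert r1.rank_p == r2.rank_p

    def test_bnd_in_window_by_either_breakpoint(self, rng):
        gene = GeneModel("g0", "chr1", 500_000, 520_000, "+")
        dos = np.clip(rng.normal(0.3, 0.2, size=60), 0, 1)
        bnd = VariantRecord("BND_00001", "BND", "chr2", 5_000_000, 5_000_001,
                            dos, chrom2="chr1", pos2=490_000)
        vm = VariantMatrix([bnd], 60)
        assert vm.cis_indices("chr1", 500_000).size == 1
        assert vm.cis_indices("chr2", 5_000_000).size == 1


class TestFdr:
    def _results(self, ps, tissue="t1"):
        out = []
        for i, p in enumerate(ps):
            lead = AssociationStat(f"v{i}", f"g{i}", tissue, 1.0, 0.1, p, 50)
            out.append(EqtlResult(f"g{i}", tissue, lead, 1, 1, p, p, 5))
        return out

    def test_hand_computed_bh(self):
        # p_i = i/1000 for i=1..20, m=20: q_i = p_i * 20 / i = 0.02 for all
        res = gene_level_fdr(self._results([i / 1000 for i in range(1, 21)]))
        assert all(r.significant for r in res)
        assert all(r.q_value == pytest.approx(0.02) for r in res)

    def test_all_ones_not_significant(self):
        res = gene_level_fdr(self._results([1.0] * 10))
        assert not any(r.significant for r in res)

    def test_single_gene_identity(self):
        (res,) = gene_level_fdr(self._results([0.05]))
        assert res.q_value == pytest.approx(0.05)
        assert res.significant

    def test_q_monotone_in_p(self, rng):
        ps = rng.uniform(size=50)
        res = gene_level_fdr(self._results(ps))
        order = np.argsort(ps)
        qs = np.array([r.q_value for r in res])[order]
        assert np.all(np.diff(qs) >= -1e-12)


class TestLeadEnrichment:
    def test_published_style_sv_fold(self):
        # 7,960 SV-led of 299,187 eQTLs over 26,409 SVs of 10,454,355 variants
        df = lead_enrichment(
            {"SV": 7_960}, {"SV": 26_409},
            total_eqtls=299_187, total_variants=10_454_355,
        )
        assert df.loc["SV", "lead_fraction"] * 100 == pytest.approx(2.66, abs=0.005)
        assert df.loc["SV", "fold"] == pytest.approx(10.5, abs=0.1)

    def test_published_style_mei_fold(self):
        df = lead_enrichment(
            {"MEI": 353}, {"MEI": 6_458},
            total_eqtls=299_187, total_variants=10_454_355,
        )
        assert df.loc["MEI", "fold"] == pytest.approx(1.9, abs=0.05)

    def test_fold_one_when_lead_share_matches_abundance(self):
        df = lead_enrichment({"DEL": 5}, {"DEL": 50}, total_eqtls=100, total_variants=1000)
        assert df.loc["DEL", "fold"] == pytest.approx(1.0)


class TestEgeneCounts:
    def _sig(self, vid, gid, tissue="t1", p=1e-4):
        lead = AssociationStat(vid, gid, tissue, 1.0, 0.1, p, 50)
        r = EqtlResult(gid, tissue, lead, 1, 1, p, p, 5)
        r.significant = True
        return r

    def test_multi_gene_sv_coding_and_noncoding_counts(self):
        genes = [
            GeneModel(f"g{i}", "chr1", 1_000 + 10_000 * i, 5_000 + 10_000 * i, "+",
                      exons=[GenomicInterval("chr1", 1_000 + 10_000 * i, 1_200 + 10_000 * i)])
            for i in range(3)
        ]
        # deletion spans g0's exon only
        sv = _make_variant("DEL_1", "DEL", "chr1", 900, 1_300, np.zeros(4))
        eqtls = [self._sig("DEL_1", f"g{i}") for i in range(3)]
        df = count_egenes_per_evariant(eqtls, genes, [sv]).set_index("variant_id")
        assert df.loc["DEL_1", "n_coding"] == 1
        assert df.loc["DEL_1", "n_noncoding"] == 2
        assert df.loc["DEL_1", "n_egenes"] == 3

    def test_snv_in_exon_is_coding(self):
        gene = GeneModel("g0", "chr1", 1_000, 5_000, "+",
                         exons=[GenomicInterval("chr1", 1_000, 1_200)])
        snv = _make_variant("SNV_1", "SNV", "chr1", 1_100, 1_101, np.zeros(4))
        df = count_egenes_per_evariant([self._sig("SNV_1", "g0")], [gene], [snv])
        assert df.iloc[0]["n_coding"] == 1 and df.iloc[0]["n_noncoding"] == 0

    def test_collapses_across_tissues(self):
        gene = GeneModel("g0", "chr1", 1_000, 5_000, "+",
                         exons=[GenomicInterval("chr1", 1_000, 1_200)])
        snv = _make_variant("SNV_1", "SNV", "chr1", 2_000, 2_001, np.zeros(4))
        eqtls = [self._sig("SNV_1", "g0", tissue=t) for t in ("t1", "t2", "t3")]
        df = count_egenes_per_evariant(eqtls, [gene], [snv])
        assert len(df) == 1 and df.iloc[0]["n_egenes"] == 1

    def test_exact_mann_whitney_enumeration(self):
        # {2,2,2} vs {1,1,1}, one-sided greater: only 1 of C(6,3)=20 orderings
        assert compare_egene_counts([2, 2, 2], [1, 1, 1]) == pytest.approx(1 / 20)


class TestBestTag:
    def test_identical_and_complement_dosages_give_r2_one(self, rng):
        d = rng.binomial(2, 0.3, 100).astype(float)
        sv = _make_variant("DEL_1", "DEL", "chr1", 0, 100, d / 2)
        snv_same = _make_variant("SNV_1", "SNV", "chr1", 50, 51, d)
        snv_comp = _make_variant("SNV_2", "SNV", "chr1", 60, 61, 2 - d)
        r2, tag = best_tag_r2(sv, [snv_same])
        assert r2 == pytest.approx(1.0)
        r2c, _ = best_tag_r2(sv, [snv_comp])
        assert r2c == pytest.approx(1.0)  # sign-invariant

    def test_null_r2_expectation(self, rng):
        n = 600
        sv = _make_variant("DEL_1", "DEL", "chr1", 0, 100,
                           np.clip(rng.normal(0.3, 0.2, n), 0, 1))
        r2s = []
        for i in range(200):
            snv = _make_variant(f"SNV_{i}", "SNV", "chr1", 0, 1,
                                rng.binomial(2, 0.3, n).astype(float))
            r2s.append(best_tag_r2(sv, [snv])[0])
        assert np.mean(r2s) == pytest.approx(1 / (n - 1), rel=0.35)

    def test_no_snv_returns_none(self, rng):
        sv = _make_variant("DEL_1", "DEL", "chr1", 0, 100, rng.uniform(size=10))
        assert best_tag_r2(sv, []) is None


def test_classify_leads_on_synthetic_results(small_cohort):
    from sveqtl.pipeline import run_eqtl

    res, vm, _ = run_eqtl(small_cohort, n_perm=150, seed=3)
    df = classify_leads(res, small_cohort.variants)
    assert "SV" in df.index
    sig = [r for r in res if r.significant]
    assert df["n_lead"].drop("SV").sum() == len(sig)
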