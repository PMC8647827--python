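import numpy as np
import pandas as pd
import pytest

from sveqtl.genio import GeneModel, VariantRecord
from sveqtl.intervals import GenomicInterval
from sveqtl.rare import (
    associate,
    association_summaries,
    find_singletons,
    odds_ratio,
    odds_ratio_by_category,
    outlier_enrichment,
    regional_burden,
    size_categories,
)

N = 30  # samples in the toy cohorts below


def _sv(vid, vclass, start, end, carrier=0, chrom="chr1", **kw):
    dos = np.zeros(N)
    if vclass == "mCNV":
        dos = np.full(N, 2.0)
        dos[carrier] = 3.0
    else:
        dos[carrier] = 0.5 if vclass in ("DEL", "DUP", "INV", "BND") else 1.0
    return VariantRecord(vid, vclass, chrom, start, end, dos, **kw)


def _gene(gid, start, end, strand="+", chrom="chr1"):
    return GeneModel(gid, chrom, start, end, strand,
                     exons=[GenomicInterval(chrom, start, min(start + 200, end))])


def _calls(rows):
    """rows: (gene_id, sample_id, classes...)"""
    recs = []
    for gid, sid, *classes in rows:
        recs.append(
            dict(gene_id=gid, sample_id=sid, n_tissues_available=5, median_z=0.0,
                 multitissue="multitissue" in classes,
                 tissue_restricted="tissue_restricted" in classes,
                 secondary="secondary" in classes or "tissue_restricted" in classes,
                 control="control" in classes)
        )
    return pd.DataFrame(recs)


SAMPLES = [f"s{i}" for i in range(N)]


class TestSingletons:
    def test_single_carrier_kept(self):
        v = _sv("a", "DEL", 0, 10_000, carrier=3)
        assert find_singletons([v]) == [v]

    def test_two_carriers_excluded(self):
        v = _sv("a", "DEL", 0, 10_000)
        v.dosages[5] = 0.5
        assert find_singletons([v]) == []

    def test_oversize_excluded_but_bnd_retained(self):
        big = _sv("big", "DEL", 0, 1_500_000)
        bnd = _sv("bnd", "BND", 0, 1, chrom2="chr2", pos2=99)
        assert find_singletons([big, bnd]) == [bnd]

    def test_mcnv_carrier_is_nonmodal_copy_number(self):
        v = _sv("m", "mCNV", 0, 50_000, carrier=7)
        (got,) = find_singletons([v])
        assert got.carriers().sum() == 1

    def test_point_variants_skipped_by_default(self):
        snv = _sv("s", "SNV", 0, 1)
        assert find_singletons([snv]) == []
        assert find_singletons([snv], sv_only=False) == [snv]


class TestAssociate:
    def test_same_sample_and_window_required(self):
        sv = _sv("a", "DEL", 100_000, 110_000, carrier=2)
        genes = [_gene("g_near", 120_000, 160_000), _gene("g_far", 700_000, 750_000)]
        calls = _calls([
            ("g_near", "s2", "multitissue"),   # carrier + in window
            ("g_far", "s2", "multitissue"),    # carrier, out of 50-kb window
            ("g_near", "s9", "multitissue"),   # wrong sample
        ])
        out = associate([sv], calls, genes, flank=50_000, sample_ids=SAMPLES)
        assert list(out["gene_id"]) == ["g_near"]
        assert list(out["sample_id"]) == ["s2"]

    def test_sv_counted_in_multiple_location_categories(self):
        # SV overlaps an exon of g0 and sits upstream of g1
        sv = _sv("a", "DUP", 99_900, 100_300, carrier=0)
        g0 = _gene("g0", 100_000, 140_000, strand="+")
        g1 = _gene("g1", 110_000, 150_000, strand="+")
        calls = _calls([("g0", "s0", "multitissue"), ("g1", "s0", "multitissue")])
        out = associate([sv], calls, [g0, g1], flank=50_000, sample_ids=SAMPLES)
        by_gene = out.set_index("gene_id")
        assert bool(by_gene.loc["g0", "coding"]) is True
        assert by_gene.loc["g0", "location"] == "overlapping-coding"
        assert bool(by_gene.loc["g1", "coding"]) is False
        assert by_gene.loc["g1", "location"] == "upstream"

    def test_strand_aware_upstream_downstream(self):
        sv = _sv("a", "DEL", 90_000, 95_000, carrier=0)
        plus = _gene("gp", 100_000, 130_000, strand="+")
        minus = _gene("gm", 100_000, 130_000, strand="-")
        calls = _calls([("gp", "s0", "multitissue"), ("gm", "s0", "multitissue")])
        out = associate([sv], calls, [plus, minus], flank=50_000, sample_ids=SAMPLES)
        loc = out.set_index("gene_id")["location"]
        assert loc["gp"] == "upstream"
        assert loc["gm"] == "downstream"
        assert (out["distance"] == 5_000).all()

    def test_summaries_reproduce_fraction_arithmetic(self):
        svs = [
            _sv("cod", "DEL", 100_000, 100_300, carrier=0),   # overlaps g0 exon
            _sv("non1", "DEL", 60_000, 61_000, carrier=1),
            _sv("non2", "DUP", 62_000, 64_000, carrier=2),
        ]
        g0 = _gene("g0", 100_000, 140_000)
        calls = _calls([
            ("g0", "s0", "multitissue"),
            ("g0", "s1", "multitissue"),
            ("g0", "s2", "multitissue"),
            ("g0", "s5", "multitissue"),  # outlier with no nearby SV
        ])
        out = associate(svs, calls, [g0], flank=50_000, sample_ids=SAMPLES)
        summ = association_summaries(out, calls)
        assert summ["n_associated_svs"] == 3
        assert summ["pct_noncoding_svs"] == pytest.approx(100 * 2 / 3)
        assert summ["pct_outliers_with_rare_sv"] == pytest.approx(75.0)


class TestOddsRatio:
    def test_direct_two_by_two_arithmetic(self):
        res = odds_ratio(20, 80, 10, 90)
        assert res["odds_ratio"] == pytest.approx(2.25)
        assert not res["corrected"]

    def test_equal_rates_give_one(self):
        assert odds_ratio(10, 90, 20, 180)["odds_ratio"] == pytest.approx(1.0)

    def test_zero_cell_haldane_correction(self):
        res = odds_ratio(0, 50, 10, 40)
        assert res["corrected"]
        assert np.isfinite(res["odds_ratio"]) and res["odds_ratio"] > 0

    def test_by_category_partition_and_bnd_size_exclusion(self):
        svs = [
            _sv("d1", "DEL", 0, 500, carrier=0),
            _sv("d2", "DEL", 0, 5_000, carrier=1),
            _sv("u1", "DUP", 0, 50_000, carrier=2),
            _sv("b1", "BND", 0, 1, carrier=3, chrom2="chr2", pos2=5),
        ]
        by_type = odds_ratio_by_category(svs, {"d1", "u1"})
        assert set(by_type.index) == {"DEL", "DUP", "BND"}
        by_size = odds_ratio_by_category(svs, {"d1", "u1"}, category_of=size_categories)
        assert "BND" not in by_size.index  # undefined size dropped
        assert set(by_size.index) == {"<1kb", "1-10kb", "10-100kb"}


class TestEnrichment:
    def _cohort(self, n_planted=10):
        svs, rows = [], []
        genes = [_gene(f"g{i}", 200_000 * i + 50_000, 200_000 * i + 80_000)
                 for i in range(12)]
        for i in range(n_planted):
            g = genes[i]
            svs.append(_sv(f"p{i}", "DEL", g.start - 3_000, g.start - 2_000, carrier=i))
            rows.append((g.gene_id, f"s{i}", "multitissue"))
        # background outliers in other samples
        for i in range(10, 12):
            rows.append((genes[i].gene_id, f"s{i + 10}", "multitissue"))
        return svs, _calls(rows), genes

    def test_planted_colocalization_detected(self):
        svs, calls, genes = self._cohort()
        res = outlier_enrichment(svs, calls, SAMPLES, genes, flanks=(5_000,),
                                 n_perm=1000, seed=0)
        row = res.iloc[0]
        assert row["observed"] == 10
        assert row["fold"] > 1
        assert row["p"] <= 0.001

    def test_fold_nonincreasing_with_flank_when_planted_close(self):
        svs, calls, genes = self._cohort()
        res = outlier_enrichment(svs, calls, SAMPLES, genes,
                                 flanks=(5_000, 25_000, 100_000), n_perm=400, seed=1)
        # all planted SVs are within 5 kb: observed stays flat while the
        # null grows with the window, so fold cannot increase
        obs = res["observed"].to_numpy()
        assert (obs == obs[0]).all()
        folds = res["fold"].replace(np.inf, np.nan).dropna().to_numpy()
        assert all(np.diff(folds) <= 1e-9)

    def test_permutation_null_preserves_outlier_marginals(self):
        """A label permutation is a bijection of samples: the total outlier
        count and each gene's outlier count are invariant."""
        rng = np.random.default_rng(0)
        O = rng.random((6, N)) < 0.2
        perm = rng.permutation(N)
        Operm = O[:, perm]
        assert Operm.sum() == O.sum()
        np.testing.assert_array_equal(Operm.sum(axis=1), O.sum(axis=1))

    def test_empty_inputs_give_empty_result(self):
        svs, calls, genes = self._cohort()
        assert outlier_enrichment([], calls, SAMPLES, genes).empty
        assert outlier_enrichment(svs, calls.iloc[0:0], SAMPLES, genes).empty


class TestRegionalBurden:
    def test_planted_three_gene_regional_effect(self):
        genes = [_gene(f"g{i}", 100_000 + 40_000 * i, 120_000 + 40_000 * i)
                 for i in range(3)]
        genes += [_gene("far", 20_000_000, 20_030_000)]
        sv = _sv("a", "DEL", 150_000, 160_000, carrier=4)
        calls = _calls([(f"g{i}", "s4", "tissue_restricted") for i in range(3)])
        res = regional_burden([sv], [], calls, SAMPLES, genes, n_perm=200, seed=0)
        assert res["assoc_primary"][0] == 3
        assert res["assoc_secondary"][0] == 3

    def test_planted_effects_beat_null_and_controls_do_not(self):
        rng = np.random.default_rng(5)
        genes = [_gene(f"g{i}", 300_000 * i + 10_000, 300_000 * i + 40_000)
                 for i in range(20)]
        assoc_svs, rows = [], []
        for i in range(12):
            g = genes[i]
            assoc_svs.append(
                _sv(f"a{i}", "DEL", g.start - 5_000, g.start - 4_000, carrier=i)
            )
            rows.append((g.gene_id, f"s{i}", "tissue_restricted"))
        control_svs = [
            _sv(f"c{i}", "DEL", genes[12 + i].start - 5_000,
                genes[12 + i].start - 4_000, carrier=20 + i)
            for i in range(6)
        ]
        calls = _calls(rows)
        res = regional_burden(assoc_svs, control_svs, calls, SAMPLES, genes,
                              n_perm=300, seed=2)
        assert res["p_assoc_vs_null_primary"] < 0.05
        assert res["mean_control_primary"] == 0.0

    def test_overlapping_sets_rejected(self):
        sv = _sv("a", "DEL", 0, 100, carrier=0)
        with pytest.raises(ValueError):
            regional_burden([sv], [sv], _calls([]), SAMPLES, [], n_perm=10)
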