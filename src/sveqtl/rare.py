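"""Rare (singleton) SV association with gene-expression outliers.

Singleton SVs — positively genotyped in exactly one individual, no larger
than 1 Mb (breakends kept, size-undefined) — are matched to expression
outliers in the same individual when the SV lies within the outlier gene's
body plus a flanking window.  Enrichment over chance is quantified by
permuting the outlier individual names 1000 times and comparing the
observed co-occurrence count with the permutation null; odds ratios by SV
type or size use Haldane–Anscombe-corrected 2x2 tables; regional burden
counts primary/secondary outliers within 1 Mb of each SV in its carrier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GeneModel, VariantRecord
from .intervals import GenomicInterval, overlaps

__all__ = [
    "find_singletons",
    "outlier_enrichment",
    "associate",
    "association_summaries",
    "odds_ratio_by_category",
    "odds_ratio",
    "size_categories",
    "regional_burden",
]

MAX_SINGLETON_SIZE = 1_000_000


def find_singletons(
    variants: list[VariantRecord],
    max_size: int = MAX_SINGLETON_SIZE,
    ab_threshold: float = 0.0,
    sv_only: bool = True,
) -> list[VariantRecord]:
    """SVs carried by exactly one individual and no larger than ``max_size``.

    "Positively genotyped" means nonzero dosage (allele balance above
    ``ab_threshold``); mCNV carriers deviate from the cohort modal copy
    number.  BNDs have no defined size and are retained regardless.
    """
    out = []
    for v in variants:
        if sv_only and not v.is_sv:
            continue
        if int(v.carriers(ab_threshold).sum()) != 1:
            continue
        if v.size is not None and v.size > max_size:
            continue
        out.append(v)
    return out


def _sv_gene_pairs(
    singletons: list[VariantRecord],
    genes: list[GeneModel],
    flank: int,
) -> list[tuple[int, int]]:
    """(singleton index, gene index) pairs where any SV breakpoint span lies
    within the gene body extended by ``flank`` on both sides."""
    pairs = []
    for si, sv in enumerate(singletons):
        for gi, g in enumerate(genes):
            if any(overlaps(iv, g.interval, flank=flank) for iv in sv.intervals):
                pairs.append((si, gi))
    return pairs


def outlier_enrichment(
    singletons: list[VariantRecord],
    calls: pd.DataFrame,
    sample_ids: list[str],
    genes: list[GeneModel],
    flanks: tuple[int, ...] = (5_000, 10_000, 25_000, 50_000, 100_000),
    n_perm: int = 1000,
    seed: int = 0,
    outlier_class: str = "multitissue",
    ab_threshold: float = 0.0,
) -> pd.DataFrame:
    """Fold enrichment of singleton SVs near expression outliers, per flank.

    Observed = number of (singleton, outlier gene/sample) co-occurrences:
    same individual, SV within gene body + flank.  The null permutes the
    outlier individual names (a bijection of the sample universe, preserving
    all marginals).  fold = observed / median(null); the 95% CI is the
    2.5-97.5 percentile band of observed/null ratios; empirical
    p = (1 + #{null >= observed}) / (n_perm + 1).  The reciprocal count
    (outliers with at least one nearby singleton) is reported alongside.
    """
    if not singletons or calls.empty:
        return pd.DataFrame()
    sample_index = {s: i for i, s in enumerate(sample_ids)}
    gene_index = {g.gene_id: i for i, g in enumerate(genes)}
    O = np.zeros((len(genes), len(sample_ids)), dtype=bool)
    sel = calls[calls[outlier_class]]
    O[
        sel["gene_id"].map(gene_index).to_numpy(),
        sel["sample_id"].map(sample_index).to_numpy(),
    ] = True
    carriers = np.array(
        [int(np.flatnonzero(v.carriers(ab_threshold))[0]) for v in singletons]
    )
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(len(sample_ids)) for _ in range(n_perm)])
    rows = []
    for flank in flanks:
        pairs = _sv_gene_pairs(singletons, genes, flank)
        if not pairs:
            rows.append(dict(flank=flank, observed=0, null_median=0.0, fold=np.nan,
                             ci_low=np.nan, ci_high=np.nan, p=1.0,
                             observed_outliers=0, null_median_outliers=0.0))
            continue
        pg = np.array([gi for _, gi in pairs])
        pc = carriers[[si for si, _ in pairs]]
        observed = int(O[pg, pc].sum())
        # outlier-side (reciprocal) count: unique outlier pairs matched
        uniq = sorted(set(zip(pg.tolist(), pc.tolist())))
        ug = np.array([g for g, _ in uniq])
        uc = np.array([c for _, c in uniq])
        observed_rec = int(O[ug, uc].sum())
        # a permutation maps outlier sample s -> perm[s]; a co-occurrence in
        # the permuted data needs O[g, inv_perm[carrier]]
        inv = np.argsort(perms, axis=1)
        null = O[pg[None, :], inv[:, pc]].sum(axis=1)
        null_rec = O[ug[None, :], inv[:, uc]].sum(axis=1)
        null_med = float(np.median(null))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = observed / null.astype(float)
        fold = observed / null_med if null_med > 0 else (np.inf if observed else np.nan)
        finite = ratios[np.isfinite(ratios)]
        ci = (
            tuple(np.percentile(finite, [2.5, 97.5])) if finite.size else (np.nan, np.nan)
        )
        p = float((1 + np.sum(null >= observed)) / (n_perm + 1))
        rows.append(
            dict(
                flank=flank, observed=observed, null_median=null_med, fold=fold,
                ci_low=ci[0], ci_high=ci[1], p=p,
                observed_outliers=observed_rec,
                null_median_outliers=float(np.median(null_rec)),
            )
        )
    return pd.DataFrame(rows)


def associate(
    singletons: list[VariantRecord],
    calls: pd.DataFrame,
    genes: list[GeneModel],
    flank: int = 50_000,
    classes: tuple[str, ...] = ("multitissue", "tissue_restricted"),
    sample_ids: list[str] | None = None,
    ab_threshold: float = 0.0,
) -> pd.DataFrame:
    """Singleton-SV / outlier associations within gene body + ``flank``.

    One row per (SV, outlier gene, outlier class): the SV's carrier must be
    the outlier individual.  ``coding`` marks SVs intersecting an exon of
    that outlier gene (flank 0); the relative location is one of
    overlapping-coding, intronic/UTR, upstream, downstream (strand-aware,
    distance from the gene-body edge).  One SV may be associated with several
    outlier genes and is counted in each category it touches.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    rows = []
    for sv in singletons:
        mask = sv.carriers(ab_threshold)
        carrier_idx = int(np.flatnonzero(mask)[0])
        carrier = sample_ids[carrier_idx] if sample_ids is not None else carrier_idx
        sub = calls[calls["sample_id"] == carrier]
        for _, call in sub.iterrows():
            g = gene_by_id.get(call["gene_id"])
            if g is None:
                continue
            if not any(overlaps(iv, g.interval, flank=flank) for iv in sv.intervals):
                continue
            coding = any(
                overlaps(iv, ex, flank=0) for iv in sv.intervals for ex in g.exons
            )
            in_body = any(overlaps(iv, g.interval, flank=0) for iv in sv.intervals)
            if coding:
                location, distance = "overlapping-coding", 0
            elif in_body:
                location, distance = "intronic/UTR", 0
            else:
                # distance from the nearest gene-body edge; upstream means the
                # TSS side of the gene on its strand
                dists = []
                for iv in sv.intervals:
                    if iv.end <= g.start:
                        dists.append((g.start - iv.end, "left"))
                    else:
                        dists.append((iv.start - g.end, "right"))
                distance, side = min(dists)
                upstream_side = "left" if g.strand == "+" else "right"
                location = "upstream" if side == upstream_side else "downstream"
            for cls in classes:
                if call[cls]:
                    rows.append(
                        dict(
                            sv_id=sv.id, sample_id=call["sample_id"],
                            gene_id=g.gene_id, outlier_class=cls, coding=coding,
                            location=location, distance=int(distance),
                            sv_class=sv.vclass,
                            sv_size=sv.size if sv.size is not None else np.nan,
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=["sv_id", "sample_id", "gene_id", "outlier_class", "coding",
                 "location", "distance", "sv_class", "sv_size"],
    )


def association_summaries(assoc: pd.DataFrame, calls: pd.DataFrame | None = None,
                          classes: tuple[str, ...] = ("multitissue", "tissue_restricted")
                          ) -> dict:
    """Headline fractions of an association table.

    Percent noncoding is over unique associated SVs (an SV is noncoding when
    it touches no exon of any of its outlier genes); percent multi-outlier is
    the share of unique SVs associated with >= 2 distinct outlier gene/sample
    pairs; size fractions (< 1 kb, < 10 kb) are per outlier class over unique
    SVs with defined size.  When ``calls`` is given, the percent of outliers
    with >= 1 rare SV is reported with both the deduplicated gene/sample-pair
    denominator and per-class denominators.
    """
    out: dict = {}
    if assoc.empty:
        return out
    assoc = assoc.assign(pair=list(zip(assoc["gene_id"], assoc["sample_id"])))
    per_sv = assoc.groupby("sv_id").agg(
        any_coding=("coding", "any"), n_outliers=("pair", "nunique")
    )
    n_sv = len(per_sv)
    out["n_associated_svs"] = n_sv
    out["pct_noncoding_svs"] = 100.0 * float((~per_sv["any_coding"]).mean())
    out["pct_svs_multiple_outliers"] = 100.0 * float((per_sv["n_outliers"] >= 2).mean())
    for cls, sub in assoc.groupby("outlier_class"):
        sizes = sub.drop_duplicates("sv_id")["sv_size"].dropna()
        if len(sizes):
            out[f"pct_lt1kb_{cls}"] = 100.0 * float((sizes < 1_000).mean())
            out[f"pct_lt10kb_{cls}"] = 100.0 * float((sizes < 10_000).mean())
    if calls is not None and not calls.empty:
        matched = set(zip(assoc["gene_id"], assoc["sample_id"]))
        dedup = calls[calls[list(classes)].any(axis=1)]
        pairs = set(zip(dedup["gene_id"], dedup["sample_id"]))
        out["pct_outliers_with_rare_sv"] = (
            100.0 * len(pairs & matched) / len(pairs) if pairs else np.nan
        )
        for cls in classes:
            sub = calls[calls[cls]]
            cpairs = set(zip(sub["gene_id"], sub["sample_id"]))
            hit = {(g, s) for g, s in cpairs
                   if (g, s) in set(zip(assoc.loc[assoc["outlier_class"] == cls, "gene_id"],
                                        assoc.loc[assoc["outlier_class"] == cls, "sample_id"]))}
            out[f"pct_outliers_with_rare_sv_{cls}"] = (
                100.0 * len(hit) / len(cpairs) if cpairs else np.nan
            )
    return out


def odds_ratio(a: int, b: int, c: int, d: int) -> dict:
    """OR = (a/b) / (c/d) with a Woolf confidence interval on log OR and the
    Haldane–Anscombe 0.5 correction when any cell is zero (flagged)."""
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = ((x + 0.5) for x in (a, b, c, d)) if corrected else (a, b, c, d)
    or_ = (aa / bb) / (cc / dd)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    lo, hi = np.exp(np.log(or_) - 1.96 * se), np.exp(np.log(or_) + 1.96 * se)
    return dict(odds_ratio=float(or_), ci_low=float(lo), ci_high=float(hi),
                corrected=corrected, a=a, b=b, c=c, d=d)


def size_categories(v: VariantRecord) -> str | None:
    """Size bin label; None for BNDs (undefined size, excluded from size ORs)."""
    if v.size is None:
        return None
    if v.size < 1_000:
        return "<1kb"
    if v.size < 10_000:
        return "1-10kb"
    if v.size < 100_000:
        return "10-100kb"
    return ">=100kb"


def odds_ratio_by_category(
    singletons: list[VariantRecord],
    associated_sv_ids: set[str],
    category_of: "callable" = lambda v: v.vclass,
) -> pd.DataFrame:
    """Per-category odds of being outlier-associated versus all singletons
    outside the category.  ``category_of`` returning None excludes a variant
    (used to drop BNDs from size-based ORs)."""
    cats: dict[str, list[VariantRecord]] = {}
    universe = []
    for v in singletons:
        c = category_of(v)
        if c is None:
            continue
        cats.setdefault(c, []).append(v)
        universe.append(v)
    rows = []
    for cat in sorted(cats):
        in_cat = cats[cat]
        out_cat = [v for v in universe if category_of(v) != cat]
        a = sum(v.id in associated_sv_ids for v in in_cat)
        b = len(in_cat) - a
        c = sum(v.id in associated_sv_ids for v in out_cat)
        d = len(out_cat) - c
        rows.append({"category": cat, **odds_ratio(a, b, c, d)})
    return pd.DataFrame(rows).set_index("category") if rows else pd.DataFrame()


def regional_burden(
    assoc_svs: list[VariantRecord],
    control_svs: list[VariantRecord],
    calls: pd.DataFrame,
    sample_ids: list[str],
    genes: list[GeneModel],
    window: int = 1_000_000,
    n_perm: int = 1000,
    seed: int = 0,
    noncoding_only: bool = False,
    ab_threshold: float = 0.0,
) -> dict:
    """Outlier burden within ``window`` bp of each SV in its carrier sample.

    Per SV: counts of primary (tissue_restricted) and secondary outlier genes
    whose gene body intersects the SV span extended by ``window``, in the
    SV's carrier.  With ``noncoding_only`` genes whose exons the SV touches
    are excluded from its counts.  The null shuffles the carrier sample names
    across the associated-SV set ``n_perm`` times and takes each SV's median
    count; group comparisons are one-sided Mann–Whitney U tests
    (associated > control, associated > null).
    """
    if {v.id for v in assoc_svs} & {v.id for v in control_svs}:
        raise ValueError("associated and control SV sets must be disjoint")
    sample_index = {s: i for i, s in enumerate(sample_ids)}
    gene_index = {g.gene_id: i for i, g in enumerate(genes)}
    P = np.zeros((len(genes), len(sample_ids)), dtype=bool)
    S = np.zeros_like(P)
    prim = calls[calls["tissue_restricted"]]
    sec = calls[calls["secondary"]]
    P[prim["gene_id"].map(gene_index), prim["sample_id"].map(sample_index)] = True
    S[sec["gene_id"].map(gene_index), sec["sample_id"].map(sample_index)] = True

    def per_sample_rows(svs):
        """For each SV, outlier counts near it for every possible sample."""
        carriers = np.empty(len(svs), dtype=int)
        prim_rows = np.zeros((len(svs), len(sample_ids)))
        sec_rows = np.zeros_like(prim_rows)
        for i, sv in enumerate(svs):
            carriers[i] = int(np.flatnonzero(sv.carriers(ab_threshold))[0])
            gidx = []
            for gi, g in enumerate(genes):
                if not any(overlaps(iv, g.interval, flank=window) for iv in sv.intervals):
                    continue
                if noncoding_only and any(
                    overlaps(iv, ex, flank=0) for iv in sv.intervals for ex in g.exons
                ):
                    continue
                gidx.append(gi)
            if gidx:
                prim_rows[i] = P[gidx].sum(axis=0)
                sec_rows[i] = S[gidx].sum(axis=0)
        return carriers, prim_rows, sec_rows

    rng = np.random.default_rng(seed)
    a_car, a_prows, a_srows = per_sample_rows(assoc_svs)
    c_car, c_prows, c_srows = per_sample_rows(control_svs)
    a_prim = a_prows[np.arange(len(assoc_svs)), a_car] if len(assoc_svs) else np.zeros(0)
    a_sec = a_srows[np.arange(len(assoc_svs)), a_car] if len(assoc_svs) else np.zeros(0)
    c_prim = c_prows[np.arange(len(control_svs)), c_car] if len(control_svs) else np.zeros(0)
    c_sec = c_srows[np.arange(len(control_svs)), c_car] if len(control_svs) else np.zeros(0)
    # null: shuffle the carrier names across the associated SVs
    if len(assoc_svs):
        perm_cols = np.stack([rng.permutation(a_car) for _ in range(n_perm)])  # n_perm x n_sv
        rows_idx = np.arange(len(assoc_svs))[None, :]
        n_prim = np.median(a_prows[rows_idx, perm_cols], axis=0)
        n_sec = np.median(a_srows[rows_idx, perm_cols], axis=0)
    else:
        n_prim = n_sec = np.zeros(0)

    def mwu(x, y):
        if len(x) == 0 or len(y) == 0:
            return np.nan
        return float(stats.mannwhitneyu(x, y, alternative="greater").pvalue)

    return dict(
        assoc_primary=a_prim, assoc_secondary=a_sec,
        control_primary=c_prim, control_secondary=c_sec,
        null_primary=n_prim, null_secondary=n_sec,
        mean_assoc_primary=float(a_prim.mean()) if len(a_prim) else np.nan,
        mean_assoc_secondary=float(a_sec.mean()) if len(a_sec) else np.nan,
        mean_null_primary=float(n_prim.mean()) if len(n_prim) else np.nan,
        mean_null_secondary=float(n_sec.mean()) if len(n_sec) else np.nan,
        mean_control_primary=float(c_prim.mean()) if len(c_prim) else np.nan,
        mean_control_secondary=float(c_sec.mean()) if len(c_sec) else np.nan,
        p_assoc_vs_control_primary=mwu(a_prim, c_prim),
        p_assoc_vs_control_secondary=mwu(a_sec, c_sec),
        p_assoc_vs_null_primary=mwu(a_prim, n_prim),
        p_assoc_vs_null_secondary=mwu(a_sec, n_sec),
    )
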