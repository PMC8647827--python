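"""High-level orchestration over a cohort bundle.

Thin conveniences that wire the stage modules together the way the analysis
runs end to end: residualize + map + FDR across tissues, causality scoring
of the strongest cis-SV per significant eGene, and cross-tissue m-value
profiles for significant eQTL pairs.
"""

from __future__ import annotations

import numpy as np

from .causality import CausalityScore, cis_h2, finemap_posterior, select_and_bin, sv_h2_fraction
from .cohort import Cohort
from .eqtl import (
    CIS_WINDOW,
    EqtlResult,
    VariantMatrix,
    gene_level_fdr,
    map_tissue,
    nominal_association,
    residualize,
)
from .genio import ExpressionPanel
from .intervals import overlaps
from .tissues import MValueProfile, build_profile

__all__ = ["run_eqtl", "score_causality", "cross_tissue_profiles"]


def run_eqtl(
    cohort: Cohort,
    n_perm: int = 1000,
    seed: int = 0,
    window: int = CIS_WINDOW,
    fdr: float = 0.10,
    maf_min: float = 0.01,
    adaptive: bool = False,
) -> tuple[list[EqtlResult], VariantMatrix, dict[str, ExpressionPanel]]:
    """Residualize every tissue, scan every gene, apply gene-level BH FDR.

    Returns the pooled results, the shared variant matrix and the
    residualized panels (reused by downstream scoring)."""
    vm = VariantMatrix(cohort.variants, len(cohort.sample_ids), maf_min=maf_min)
    ss = np.random.SeedSequence(seed)
    tissue_seeds = dict(zip(cohort.tissues, ss.generate_state(len(cohort.tissues))))
    results: list[EqtlResult] = []
    resid_panels: dict[str, ExpressionPanel] = {}
    for tissue in cohort.tissues:
        pr = residualize(cohort.panels[tissue], cohort.covariates)
        resid_panels[tissue] = pr
        results.extend(
            map_tissue(
                cohort.genes, vm, pr, n_perm=n_perm,
                seed=int(tissue_seeds[tissue] % (2**31)), window=window,
                adaptive=adaptive,
            )
        )
    return gene_level_fdr(results, fdr=fdr), vm, resid_panels


def score_causality(
    cohort: Cohort,
    eqtls: list[EqtlResult],
    vm: VariantMatrix,
    resid_panels: dict[str, ExpressionPanel],
    window: int = CIS_WINDOW,
    prior_effect_sd: float = 0.5,
) -> tuple[list[CausalityScore], list[tuple[str, str]]]:
    """Causality score of the strongest-associated cis-SV of each significant
    eGene/tissue pair, deduplicated per SV and quantile-binned.

    Returns (binned scores, excluded gene/tissue pairs).  Exclusions are
    eGenes whose heritability estimation failed (too few samples or a
    degenerate cis relatedness matrix), mirroring how loci without usable
    heritability estimates are dropped from enrichment analyses.
    """
    scores: list[CausalityScore] = []
    excluded: list[tuple[str, str]] = []
    sv_mask = np.array([v.is_sv for v in vm.variants])
    for r in eqtls:
        if not r.significant:
            continue
        gene = cohort.gene(r.gene_id)
        idx = vm.cis_indices(gene.chrom, gene.tss, window)
        if idx.size == 0 or not sv_mask[idx].any():
            continue
        y = resid_panels[r.tissue].values.loc[r.gene_id].to_numpy(dtype=float)
        yc = y - y.mean()
        ynorm = np.linalg.norm(yc)
        if ynorm == 0:
            excluded.append((r.gene_id, r.tissue))
            continue
        n = y.size
        df = n - 2
        rr = (vm.Dc[idx] @ yc) / (vm.norms[idx] * ynorm)
        rr = np.clip(rr, -1 + 1e-12, 1 - 1e-12)
        z = rr * np.sqrt(df / (1 - rr**2))
        se_std = np.sqrt((1 - rr**2) / df)
        post = finemap_posterior(z, prior_effect_sd=prior_effect_sd, ses=se_std)
        cis_sv_local = np.flatnonzero(sv_mask[idx])
        # strongest cis-SV: largest |z|
        best = cis_sv_local[int(np.argmax(np.abs(z[cis_sv_local])))]
        sv = vm.variants[idx[best]]
        try:
            h2 = cis_h2(y, vm.D[idx])
        except ValueError:
            excluded.append((r.gene_id, r.tissue))
            continue
        frac = sv_h2_fraction(sv.dosages, y, h2)
        scores.append(
            CausalityScore(
                sv_id=sv.id, gene_id=r.gene_id, tissue=r.tissue,
                posterior=float(post[best]), h2_cis=h2, h2_sv_fraction=frac,
                score=float(post[best]) * frac,
            )
        )
    return select_and_bin(scores), excluded


def cross_tissue_profiles(
    cohort: Cohort,
    eqtls: list[EqtlResult],
    resid_panels: dict[str, ExpressionPanel],
    prior_active: float = 0.5,
    prior_effect_sd: float = 0.3,
) -> list[MValueProfile]:
    """m-value profile of every unique significant eVariant/eGene pair across
    all tissues, grouped as coding SV / noncoding SV / SNV+indel by exon
    overlap with the eGene."""
    pairs = sorted(
        {(r.lead.variant_id, r.gene_id) for r in eqtls if r.significant}
    )
    profiles = []
    for vid, gid in pairs:
        v = cohort.variant(vid)
        gene = cohort.gene(gid)
        betas, ses = [], []
        for t in cohort.tissues:
            y = resid_panels[t].values.loc[gid].to_numpy(dtype=float)
            try:
                st = nominal_association(v.dosages, y, vid, gid, t)
                betas.append(st.slope)
                ses.append(st.slope_se)
            except ValueError:
                betas.append(np.nan)
                ses.append(np.nan)
        coding = any(
            overlaps(vi, ex, flank=0) for vi in v.intervals for ex in gene.exons
        )
        if v.is_sv:
            group = "coding_SV" if coding else "noncoding_SV"
        else:
            group = "coding_SNV_indel" if coding else "noncoding_SNV_indel"
        profiles.append(
            build_profile(
                vid, gid, cohort.tissues, np.array(betas), np.array(ses),
                group=group, prior_active=prior_active,
                prior_effect_sd=prior_effect_sd,
            )
        )
    return profiles
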