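"""Joint multi-class cis-eQTL mapping.

For each gene, all common variants (SVs, SNVs, indels, MEIs together, so
classes compete for lead status) whose interval — either breakpoint for a
BND — lies within the cis window of the TSS are tested by simple linear
regression of covariate-residualized expression on dosage.  The lead marker
is the smallest nominal p; its gene-level empirical p-value comes from a
permutation null of lead p-values approximated by a maximum-likelihood beta
fit (the FastQTL-style approximation), with gene-level Benjamini–Hochberg
FDR within each tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betainc, digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .genio import ExpressionPanel, GeneModel, VariantRecord, SV_CLASSES
from .intervals import GenomicInterval, overlaps

__all__ = [
    "AssociationStat",
    "EqtlResult",
    "MonomorphicError",
    "residualize",
    "nominal_association",
    "VariantMatrix",
    "map_cis_gene",
    "map_tissue",
    "fit_beta_null",
    "beta_empirical_p",
    "gene_level_fdr",
    "classify_leads",
    "lead_enrichment",
    "count_egenes_per_evariant",
    "compare_egene_counts",
    "best_tag_r2",
]

CIS_WINDOW = 1_000_000


class MonomorphicError(ValueError):
    """Dosage has zero variance; the variant cannot be tested."""


@dataclass
class AssociationStat:
    variant_id: str
    gene_id: str
    tissue: str
    slope: float
    slope_se: float
    nominal_p: float
    n: int


@dataclass
class EqtlResult:
    gene_id: str
    tissue: str
    lead: AssociationStat
    beta_shape1: float
    beta_shape2: float
    empirical_p: float
    rank_p: float
    n_cis: int
    q_value: float = np.nan
    significant: bool = False


def residualize(panel: ExpressionPanel, covariates: pd.DataFrame) -> ExpressionPanel:
    """Replace each gene's expression by OLS residuals against the covariates
    plus an intercept.  Collinear covariate columns are dropped with a
    warning."""
    Y = panel.values.to_numpy(dtype=float)
    C = covariates.loc[panel.sample_ids].to_numpy(dtype=float)
    X = np.column_stack([np.ones(C.shape[0]), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        keep = [0]
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, keep + [j]]) > len(keep):
                keep.append(j)
        dropped = X.shape[1] - len(keep)
        warnings.warn(f"dropped {dropped} collinear covariate column(s)", stacklevel=2)
        X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y - (X @ beta).T
    return ExpressionPanel(
        tissue=panel.tissue,
        values=pd.DataFrame(resid, index=panel.values.index, columns=panel.values.columns),
    )


def nominal_association(
    dosage: np.ndarray,
    expression: np.ndarray,
    variant_id: str = "",
    gene_id: str = "",
    tissue: str = "",
) -> AssociationStat:
    """Simple linear regression of expression on dosage (pairwise-complete),
    with a two-sided t-test on the slope (df = n - 2)."""
    d = np.asarray(dosage, dtype=float)
    y = np.asarray(expression, dtype=float)
    ok = ~(np.isnan(d) | np.isnan(y))
    d, y = d[ok], y[ok]
    n = d.size
    if n < 3:
        raise ValueError("need at least 3 complete observations")
    dc = d - d.mean()
    yc = y - y.mean()
    sxx = float(dc @ dc)
    if sxx == 0:
        raise MonomorphicError(f"variant {variant_id or '?'} has zero dosage variance")
    slope = float(dc @ yc) / sxx
    df = n - 2
    rss = float(yc @ yc) - slope * float(dc @ yc)
    rss = max(rss, 0.0)
    se = np.sqrt(rss / df / sxx) if df > 0 else np.nan
    if se == 0 or df <= 0:
        p = 0.0 if slope != 0 else 1.0
        se = max(se, np.finfo(float).tiny)
    else:
        t = slope / se
        p = float(2 * stats.t.sf(abs(t), df))
    return AssociationStat(
        variant_id=variant_id, gene_id=gene_id, tissue=tissue,
        slope=slope, slope_se=float(se), nominal_p=max(p, np.finfo(float).tiny), n=n,
    )


def _p_from_absr(abs_r: np.ndarray, df: int) -> np.ndarray:
    """Two-sided p-value of the regression t-test from |correlation|.

    Uses the regularized incomplete beta identity p = I_{df/(df+t^2)}(df/2, 1/2),
    which is monotone in |r| and stable for |r| near 1.
    """
    abs_r = np.clip(abs_r, 0.0, 1.0 - 1e-15)
    t2 = df * abs_r**2 / (1.0 - abs_r**2)
    return betainc(df / 2.0, 0.5, df / (df + t2))


class VariantMatrix:
    """Dense dosage matrix over a fixed sample order with cis lookup.

    Missing dosages are mean-imputed for the vectorized permutation pass; the
    reported lead statistics are recomputed pairwise-complete.
    """

    def __init__(self, variants: list[VariantRecord], n_samples: int, maf_min: float = 0.01):
        self.variants = [v for v in variants if v.maf >= maf_min and np.nanstd(v.dosages) > 0]
        self.ids = np.array([v.id for v in self.variants])
        m = len(self.variants)
        D = np.empty((m, n_samples))
        for i, v in enumerate(self.variants):
            d = v.dosages.astype(float)
            if np.isnan(d).any():
                d = np.where(np.isnan(d), np.nanmean(d), d)
            D[i] = d
        self.D = D
        self.Dc = D - D.mean(axis=1, keepdims=True)
        self.norms = np.linalg.norm(self.Dc, axis=1)
        # one row per breakpoint span (two for BNDs) for cis-window lookup
        span_chrom, span_lo, span_hi, span_idx = [], [], [], []
        for i, v in enumerate(self.variants):
            for iv in v.intervals:
                span_chrom.append(iv.chrom)
                span_lo.append(iv.start)
                span_hi.append(iv.end)
                span_idx.append(i)
        self._span_chrom = np.array(span_chrom)
        self._span_lo = np.array(span_lo)
        self._span_hi = np.array(span_hi)
        self._span_idx = np.array(span_idx, dtype=int)

    def cis_indices(self, chrom: str, tss: int, window: int = CIS_WINDOW) -> np.ndarray:
        """Variants whose interval (either BND breakpoint) intersects
        [tss - window, tss + window)."""
        mask = (
            (self._span_chrom == chrom)
            & (self._span_lo < tss + window)
            & (self._span_hi > tss - window)
        )
        return np.unique(self._span_idx[mask])


def fit_beta_null(null_min_pvalues: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Beta(a, b) fit to permutation null lead p-values.

    Moment initialization followed by Newton iterations on the digamma score
    equations.  Requires >= 50 null minima strictly inside (0, 1); a
    degenerate (all-equal) null raises ValueError so callers can fall back to
    the rank-based p-value.
    """
    x = np.asarray(null_min_pvalues, dtype=float)
    if x.size < 50:
        raise ValueError(f"need >= 50 null minima, got {x.size}")
    if np.any((x <= 0) | (x >= 1)):
        x = np.clip(x, 1e-300, 1 - 1e-16)
    if np.allclose(x, x[0]):
        raise ValueError("degenerate permutation null (all minima equal)")
    m, v = x.mean(), x.var()
    v = max(v, 1e-12)
    common = m * (1 - m) / v - 1.0
    a = max(m * common, 1e-3)
    b = max((1 - m) * common, 1e-3)
    g1 = np.mean(np.log(x))
    g2 = np.mean(np.log1p(-x))
    for _ in range(100):
        psi_ab = digamma(a + b)
        f1 = digamma(a) - psi_ab - g1
        f2 = digamma(b) - psi_ab - g2
        tri_ab = polygamma(1, a + b)
        j11 = polygamma(1, a) - tri_ab
        j22 = polygamma(1, b) - tri_ab
        j12 = -tri_ab
        det = j11 * j22 - j12 * j12
        if abs(det) < 1e-300:
            break
        da = (f1 * j22 - f2 * j12) / det
        db = (f2 * j11 - f1 * j12) / det
        a_new = max(a - da, 1e-6)
        b_new = max(b - db, 1e-6)
        if abs(a_new - a) < 1e-10 * a and abs(b_new - b) < 1e-10 * b:
            a, b = a_new, b_new
            break
        a, b = a_new, b_new
    return float(a), float(b)


def beta_empirical_p(observed_p: float, shape1: float, shape2: float) -> float:
    return float(stats.beta.cdf(observed_p, shape1, shape2))


def _lead_order_key(stat: AssociationStat, variant: VariantRecord):
    return (stat.nominal_p, -abs(stat.slope), variant.start, variant.id)


def map_cis_gene(
    gene: GeneModel,
    vm: VariantMatrix,
    panel: ExpressionPanel,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    window: int = CIS_WINDOW,
    adaptive: bool = False,
    adaptive_min_hits: int = 100,
) -> EqtlResult | None:
    """Permutation cis-eQTL scan for one gene on a residualized panel.

    Returns None when the cis set is empty.  Permutations shuffle expression
    across samples jointly against all cis variants; the empirical p is the
    beta-CDF of the lead nominal p under the fitted permutation null.  With
    ``adaptive`` the permutation loop stops early once ``adaptive_min_hits``
    null lead p-values beat the observed lead.  Deterministic under seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = vm.cis_indices(gene.chrom, gene.tss, window)
    if idx.size == 0:
        return None
    y = panel.values.loc[gene.gene_id].to_numpy(dtype=float)
    yc = y - y.mean()
    ynorm = np.linalg.norm(yc)
    if ynorm == 0:
        return None
    n = y.size
    df = n - 2
    Dc = vm.Dc[idx]
    norms = vm.norms[idx]
    r_obs = (Dc @ yc) / (norms * ynorm)
    p_obs = _p_from_absr(np.abs(r_obs), df)
    best_local = int(np.argmin(p_obs))
    # tie-break: smallest p, largest |slope|, leftmost position, lexicographic id
    ties = np.flatnonzero(p_obs <= p_obs[best_local] * (1 + 1e-12))
    if ties.size > 1:
        stats_ties = []
        for j in ties:
            v = vm.variants[idx[j]]
            s = nominal_association(vm.D[idx[j]], y, v.id, gene.gene_id, panel.tissue)
            stats_ties.append((_lead_order_key(s, v), int(j)))
        best_local = min(stats_ties)[1]
    lead_variant = vm.variants[idx[best_local]]
    lead = nominal_association(
        lead_variant.dosages, y, lead_variant.id, gene.gene_id, panel.tissue
    )
    obs_p = float(p_obs[best_local])

    null_min: list[np.ndarray] = []
    hits = 0
    done = 0
    block = 100 if adaptive else n_perm
    while done < n_perm:
        b = min(block, n_perm - done)
        Yp = rng.permuted(np.broadcast_to(yc, (b, n)), axis=1).T
        R = (Dc @ Yp) / (norms[:, None] * ynorm)
        max_abs_r = np.max(np.abs(R), axis=0)
        pmins = _p_from_absr(max_abs_r, df)
        null_min.append(pmins)
        done += b
        hits += int(np.sum(pmins <= obs_p))
        if adaptive and hits >= adaptive_min_hits:
            break
    null_p = np.concatenate(null_min)
    rank_p = (1.0 + np.sum(null_p <= obs_p)) / (null_p.size + 1.0)
    try:
        a, b_shape = fit_beta_null(null_p)
        emp_p = beta_empirical_p(obs_p, a, b_shape)
    except ValueError as exc:
        warnings.warn(f"{gene.gene_id}: {exc}; falling back to rank p", stacklevel=2)
        a = b_shape = np.nan
        emp_p = rank_p
    return EqtlResult(
        gene_id=gene.gene_id,
        tissue=panel.tissue,
        lead=lead,
        beta_shape1=a,
        beta_shape2=b_shape,
        empirical_p=max(emp_p, np.finfo(float).tiny),
        rank_p=rank_p,
        n_cis=int(idx.size),
    )


def map_tissue(
    genes: list[GeneModel],
    vm: VariantMatrix,
    panel_resid: ExpressionPanel,
    n_perm: int = 1000,
    seed: int = 0,
    window: int = CIS_WINDOW,
    adaptive: bool = False,
) -> list[EqtlResult]:
    """Scan every gene in one residualized tissue panel; per-gene child seeds
    come from a single SeedSequence so results are order-independent."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(genes))
    out = []
    for gene, child in zip(genes, children):
        res = map_cis_gene(
            gene, vm, panel_resid, n_perm=n_perm,
            seed=np.random.default_rng(child), window=window, adaptive=adaptive,
        )
        if res is not None:
            out.append(res)
    return out


def gene_level_fdr(results: list[EqtlResult], fdr: float = 0.10) -> list[EqtlResult]:
    """Benjamini–Hochberg within each tissue; ``q_value`` is the BH-adjusted
    empirical p and ``significant`` marks q <= fdr."""
    by_tissue: dict[str, list[EqtlResult]] = {}
    for r in results:
        by_tissue.setdefault(r.tissue, []).append(r)
    for tissue_results in by_tissue.values():
        ps = np.array([r.empirical_p for r in tissue_results])
        _, qs, *_ = multipletests(ps, alpha=fdr, method="fdr_bh")
        for r, q in zip(tissue_results, qs):
            r.q_value = float(q)
            r.significant = bool(q <= fdr)
    return results


def lead_enrichment(
    lead_counts: dict[str, int],
    catalog_counts: dict[str, int],
    total_eqtls: int | None = None,
    total_variants: int | None = None,
) -> pd.DataFrame:
    """Lead-marker share versus genomic abundance per variant class.

    ``lead fraction = eQTLs led by the class / total eQTLs``;
    ``abundance fraction = class count / total common variants``;
    ``fold = lead fraction / abundance fraction``.  Totals default to the
    sums of the supplied counts.
    """
    tot_e = total_eqtls if total_eqtls is not None else sum(lead_counts.values())
    tot_v = total_variants if total_variants is not None else sum(catalog_counts.values())
    rows = []
    for cls in catalog_counts:
        lead_frac = lead_counts.get(cls, 0) / tot_e if tot_e else np.nan
        abund = catalog_counts[cls] / tot_v if tot_v else np.nan
        rows.append(
            {
                "class": cls,
                "n_lead": lead_counts.get(cls, 0),
                "n_catalog": catalog_counts[cls],
                "lead_fraction": lead_frac,
                "abundance_fraction": abund,
                "fold": lead_frac / abund if abund else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("class")


def classify_leads(
    eqtls: list[EqtlResult], variants: list[VariantRecord], group_svs: bool = True
) -> pd.DataFrame:
    """Per-class lead counts / fractions / fold enrichment over abundance for
    the significant eQTL set.  With ``group_svs`` an aggregate ``SV`` row
    (DEL+DUP+mCNV+INV+BND+MEI) is appended."""
    sig = [r for r in eqtls if r.significant]
    if not sig:
        return pd.DataFrame(
            columns=["n_lead", "n_catalog", "lead_fraction", "abundance_fraction", "fold"]
        )
    vclass = {v.id: v.vclass for v in variants}
    lead_counts: dict[str, int] = {}
    for r in sig:
        cls = vclass[r.lead.variant_id]
        lead_counts[cls] = lead_counts.get(cls, 0) + 1
    catalog_counts: dict[str, int] = {}
    for v in variants:
        catalog_counts[v.vclass] = catalog_counts.get(v.vclass, 0) + 1
    df = lead_enrichment(lead_counts, catalog_counts)
    if group_svs:
        sv_lead = sum(lead_counts.get(c, 0) for c in SV_CLASSES)
        sv_cat = sum(catalog_counts.get(c, 0) for c in SV_CLASSES)
        agg = lead_enrichment(
            {"SV": sv_lead}, {"SV": sv_cat},
            total_eqtls=len(sig), total_variants=sum(catalog_counts.values()),
        )
        df = pd.concat([df, agg])
    return df


def count_egenes_per_evariant(
    eqtls: list[EqtlResult],
    genes: list[GeneModel],
    variants: list[VariantRecord],
) -> pd.DataFrame:
    """Per-eVariant counts of coding and noncoding eGenes, collapsed across
    tissues on unique eGene/eVariant pairs.

    A coding eGene has at least one exon overlapped by the eVariant (flank 0,
    either BND breakpoint); a noncoding eGene does not.  eGenes without exon
    models are excluded with a warning.
    """
    sig = [r for r in eqtls if r.significant]
    gene_by_id = {g.gene_id: g for g in genes}
    var_by_id = {v.id: v for v in variants}
    pairs: set[tuple[str, str]] = set()
    for r in sig:
        pairs.add((r.lead.variant_id, r.gene_id))
    rows = []
    per_variant: dict[str, dict[str, int]] = {}
    for vid, gid in sorted(pairs):
        gene = gene_by_id.get(gid)
        if gene is None or not gene.exons:
            warnings.warn(f"eGene {gid} has no exon model; excluded", stacklevel=2)
            continue
        v = var_by_id[vid]
        coding = any(
            overlaps(vi, ex, flank=0) for vi in v.intervals for ex in gene.exons
        )
        d = per_variant.setdefault(vid, {"coding": 0, "noncoding": 0})
        d["coding" if coding else "noncoding"] += 1
    for vid, d in per_variant.items():
        v = var_by_id[vid]
        rows.append(
            {
                "variant_id": vid,
                "vclass": v.vclass,
                "is_sv": v.is_sv,
                "n_coding": d["coding"],
                "n_noncoding": d["noncoding"],
                "n_egenes": d["coding"] + d["noncoding"],
            }
        )
    return pd.DataFrame(rows)


def compare_egene_counts(counts_a: np.ndarray, counts_b: np.ndarray) -> float:
    """One-sided Mann–Whitney U p-value that distribution a is stochastically
    greater than b.

    For small samples (n_a + n_b <= 14) the null is enumerated exactly over
    all group assignments of the pooled values (ties handled by the 1/2
    convention in U); larger samples use the normal approximation with tie
    correction."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size + b.size <= 14:
        from itertools import combinations

        pooled = np.concatenate([a, b])
        idx = range(pooled.size)

        def ustat(mask_a):
            xs = pooled[list(mask_a)]
            ys = np.delete(pooled, list(mask_a))
            return np.sum(xs[:, None] > ys[None, :]) + 0.5 * np.sum(
                xs[:, None] == ys[None, :]
            )

        observed = ustat(range(a.size))
        hits = total = 0
        for comb in combinations(idx, a.size):
            total += 1
            hits += ustat(comb) >= observed - 1e-12
        return hits / total
    return float(stats.mannwhitneyu(a, b, alternative="greater").pvalue)


def best_tag_r2(
    sv: VariantRecord, snvs_in_window: list[VariantRecord]
) -> tuple[float, str] | None:
    """Max squared Pearson correlation (pairwise-complete) between the SV
    dosage and any SNV dosage in the window, with the tagging SNV id.
    Returns None when no SNV is available."""
    if not snvs_in_window:
        return None
    best = (-1.0, "")
    x = sv.dosages.astype(float)
    for snv in snvs_in_window:
        y = snv.dosages.astype(float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3:
            continue
        xs, ys = x[ok], y[ok]
        if xs.std() == 0 or ys.std() == 0:
            continue
        r = np.corrcoef(xs, ys)[0, 1]
        r2 = float(r * r)
        if r2 > best[0]:
            best = (r2, snv.id)
    if best[0] < 0:
        return None
    return best
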