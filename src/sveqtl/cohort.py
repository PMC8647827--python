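"""Synthetic multi-tissue cohort generator.

Emulates the structure of a WGS + multi-tissue RNA-seq cohort: common
variants of eight classes (DEL/DUP/mCNV/INV/BND/MEI/SNV/INDEL) with exact
allele frequencies in a configured MAF range, rare singleton SVs carried by
exactly one sample, per-tissue expression panels with covariate structure,
gene models with exons, and a machine-readable truth table of every planted
effect.  Expression is generated on a continuous, already covariate-scale
("PEER-corrected") scale:

    y[g, t, s] = baseline[g] + covariates[s] . loadings[g, t]
                 + sum over planted cis effects of slope * dosage[v, s]
                 + Normal(0, noise_sd)

Rare outlier effects additionally shift the carrier sample's expression of
the target genes by ``direction * magnitude * noise_sd``.  A single global
seed expands into independent per-component child streams through
``numpy.random.SeedSequence.spawn``, so the same seed yields a byte-identical
bundle on disk.

SV dosages are allele balance in [0, 1] (integer copy number 0-6 with cohort
mode 2 for mCNVs); SNVs, indels and MEIs carry allele counts 0/1/2.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genio import (
    AB_CLASSES,
    CN_CLASSES,
    ExpressionPanel,
    GeneModel,
    VariantRecord,
    read_covariates,
    read_expression,
    read_gene_models,
    read_variants,
    write_covariates,
    write_expression,
    write_gene_models,
    write_variants,
)
from .intervals import GenomicInterval, overlaps

__all__ = [
    "CohortConfig",
    "EqtlEffect",
    "RareOutlierEffect",
    "PlantedOutlier",
    "TruthTable",
    "Cohort",
    "ConfigError",
    "generate_cohort",
    "generate_feature_tracks",
]

CIS_WINDOW = 1_000_000


class ConfigError(ValueError):
    """Infeasible or inconsistent cohort configuration."""


@dataclass
class EqtlEffect:
    """A planted common-variant cis effect: ``slope`` expression units per
    dosage unit on each gene in ``gene_ids``, in ``tissues`` (None = all)."""

    variant_id: str
    gene_ids: tuple[str, ...]
    slope: float
    tissues: tuple[str, ...] | None = None
    coding: bool = False


@dataclass
class RareOutlierEffect:
    """A planted singleton-SV expression-outlier effect on the carrier."""

    variant_id: str
    gene_ids: tuple[str, ...]
    direction: int  # +1 over-expression, -1 under-expression
    magnitude: float = 6.0  # in noise-sd units
    coding: bool = False


@dataclass
class PlantedOutlier:
    variant_id: str
    sample_id: str
    gene_ids: tuple[str, ...]
    direction: int
    coding: bool


@dataclass
class TruthTable:
    eqtls: list[EqtlEffect] = field(default_factory=list)
    outliers: list[PlantedOutlier] = field(default_factory=list)
    functional_sv_ids: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "eqtls": [asdict(e) for e in self.eqtls],
            "outliers": [asdict(o) for o in self.outliers],
            "functional_sv_ids": list(self.functional_sv_ids),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        payload = json.loads(Path(path).read_text())
        eqtls = [
            EqtlEffect(
                variant_id=e["variant_id"],
                gene_ids=tuple(e["gene_ids"]),
                slope=e["slope"],
                tissues=None if e["tissues"] is None else tuple(e["tissues"]),
                coding=e["coding"],
            )
            for e in payload["eqtls"]
        ]
        outliers = [
            PlantedOutlier(
                variant_id=o["variant_id"],
                sample_id=o["sample_id"],
                gene_ids=tuple(o["gene_ids"]),
                direction=o["direction"],
                coding=o["coding"],
            )
            for o in payload["outliers"]
        ]
        return cls(eqtls=eqtls, outliers=outliers, functional_sv_ids=payload["functional_sv_ids"])


_DEFAULT_CLASS_COUNTS = {
    "DEL": 150,
    "DUP": 60,
    "mCNV": 30,
    "INV": 15,
    "BND": 15,
    "MEI": 30,
    "SNV": 2400,
    "INDEL": 300,
}


@dataclass
class CohortConfig:
    """Study-condition knobs for the synthetic cohort.

    Defaults give the desk-scale cohort used throughout the test suites:
    200 samples, 5 tissues, 300 genes and 3000 common variants on a 2 x 25 Mb
    genome with one central assembly gap per chromosome.
    """

    n_samples: int = 200
    n_tissues: int = 5
    n_genes: int = 300
    n_chromosomes: int = 2
    chrom_length: int = 25_000_000
    gap_length: int = 500_000
    class_counts: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_CLASS_COUNTS))
    maf_range: tuple[float, float] = (0.01, 0.5)
    n_covariates: int = 3
    noise_sd: float = 1.0
    baseline_mean: float = 0.0
    baseline_sd: float = 1.0
    floor_at_zero: bool = False
    # planted common cis effects: explicit specs, or auto-planting knobs
    eqtl_effects: list[EqtlEffect] | None = None
    n_eqtl_effects: int = 0
    effect_slope: float = 3.0
    eqtl_sv_fraction: float = 0.5  # share of auto-planted effects on SV classes
    multi_gene_fraction: float = 0.3
    tissue_restricted_fraction: float = 0.3
    coding_fraction: float = 0.3
    # rare singleton SVs and planted outlier effects
    n_rare_svs: int = 0
    rare_effects: list[RareOutlierEffect] | None = None
    n_rare_outlier_effects: int = 0
    outlier_magnitude: float = 6.0
    rare_coding_fraction: float = 0.4
    rare_regional_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_samples", "n_tissues", "n_genes", "n_chromosomes", "chrom_length"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not (0.01 <= self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ConfigError("maf_range must lie within [0.01, 0.5] (common variants)")
        if any(c < 0 for c in self.class_counts.values()):
            raise ConfigError("class counts must be non-negative")
        n_common = sum(self.class_counts.values())
        n_explicit = len(self.eqtl_effects) if self.eqtl_effects else self.n_eqtl_effects
        if n_explicit > n_common:
            raise ConfigError("more planted eQTL effects than common variants")
        n_rare_fx = len(self.rare_effects) if self.rare_effects else self.n_rare_outlier_effects
        if n_rare_fx > max(self.n_rare_svs, len(self.rare_effects or [])):
            raise ConfigError("more rare outlier effects than rare SVs")
        if (self.n_rare_svs > 0 or n_rare_fx > 0) and self.n_samples < 2:
            raise ConfigError("singleton SVs require at least 2 samples")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")


@dataclass
class Cohort:
    """The generated bundle: everything downstream stages consume."""

    sample_ids: list[str]
    tissues: list[str]
    genome: dict[str, int]
    gaps: list[GenomicInterval]
    genes: list[GeneModel]
    variants: list[VariantRecord]
    panels: dict[str, ExpressionPanel]
    covariates: pd.DataFrame
    truth: TruthTable
    config: CohortConfig | None = None

    def variant(self, vid: str) -> VariantRecord:
        return self._by_id[vid]

    def gene(self, gid: str) -> GeneModel:
        return self._genes_by_id[gid]

    def __post_init__(self) -> None:
        self._by_id = {v.id: v for v in self.variants}
        self._genes_by_id = {g.gene_id: g for g in self.genes}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_variants(self.variants, self.sample_ids, outdir / "variants.vcf", contigs=self.genome)
        write_gene_models(self.genes, outdir / "genes.bed")
        for tissue, panel in self.panels.items():
            write_expression(panel, outdir / f"expression.{tissue}.tsv")
        write_covariates(self.covariates, outdir / "covariates.tsv")
        self.truth.to_json(outdir / "truth.json")
        meta = {
            "genome": self.genome,
            "gaps": [[g.chrom, g.start, g.end] for g in self.gaps],
            "tissues": self.tissues,
            "sample_ids": self.sample_ids,
        }
        (outdir / "genome.json").write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")

    @classmethod
    def read(cls, indir: str | Path) -> "Cohort":
        indir = Path(indir)
        meta = json.loads((indir / "genome.json").read_text())
        panels = {
            t: read_expression(indir / f"expression.{t}.tsv", t) for t in meta["tissues"]
        }
        return cls(
            sample_ids=meta["sample_ids"],
            tissues=meta["tissues"],
            genome=meta["genome"],
            gaps=[GenomicInterval(c, s, e) for c, s, e in meta["gaps"]],
            genes=read_gene_models(indir / "genes.bed"),
            variants=read_variants(indir / "variants.vcf"),
            panels=panels,
            covariates=read_covariates(indir / "covariates.tsv"),
            truth=TruthTable.from_json(indir / "truth.json"),
        )


# ---------------------------------------------------------------------------
# generation internals


def _sample_position(rng, genome, gaps, length, chrom=None):
    chroms = list(genome)
    lens = np.array([genome[c] for c in chroms], dtype=float)
    fits = np.maximum(lens - length + 1, 0)
    if fits.sum() == 0:
        raise ConfigError(f"no chromosome can hold an interval of {length} bp")
    w = fits / fits.sum()
    for _ in range(10_000):
        c = chrom if chrom is not None else chroms[rng.choice(len(chroms), p=w)]
        start = int(rng.integers(0, genome[c] - length + 1))
        probe = GenomicInterval(c, start, start + length)
        if not any(overlaps(probe, g) for g in gaps):
            return c, start
    raise ConfigError("could not place interval outside gaps")


def _exact_genotypes(rng, n, maf_lo, maf_hi):
    """Allele-count genotypes with realized AF exactly inside the MAF range."""
    p = rng.uniform(maf_lo, maf_hi)
    ac = int(round(2 * n * p))
    ac = int(np.clip(ac, math.ceil(2 * n * maf_lo), math.floor(2 * n * maf_hi)))
    alleles = np.zeros(2 * n, dtype=int)
    alleles[:ac] = 1
    rng.shuffle(alleles)
    return alleles.reshape(n, 2).sum(axis=1)


def _ab_from_gt(rng, gt):
    """Allele balance from allele counts: 0/1/2 -> 0 / ~0.5 / 1, with
    heterozygote noise centred exactly so mean(AB) equals the allele
    frequency (keeps realized MAF inside the configured range)."""
    ab = gt / 2.0
    het = gt == 1
    if het.any():
        e = rng.normal(0, 0.05, size=int(het.sum()))
        e -= e.mean()
        ab[het] = np.clip(0.5 + e, 0.2, 0.8)
    return ab


_LEN_RANGES = {  # log10 bp
    "DEL": (1.7, 5.0),
    "DUP": (2.0, 5.0),
    "INV": (2.0, 5.0),
    "mCNV": (3.0, 5.3),
}


def _variant_length(rng, vclass):
    if vclass == "SNV":
        return 1
    if vclass == "INDEL":
        return int(rng.integers(1, 50))
    if vclass == "MEI":
        return int(rng.choice([300, 6000, 3000], p=[0.7, 0.15, 0.15]))
    if vclass == "BND":
        return 1
    lo, hi = _LEN_RANGES[vclass]
    return int(round(10 ** rng.uniform(lo, hi)))


def _make_common_variant(rng, vclass, idx, n, genome, gaps, maf_range):
    length = _variant_length(rng, vclass)
    chrom, start = _sample_position(rng, genome, gaps, length)
    vid = f"{vclass}_{idx:05d}"
    chrom2 = pos2 = None
    if vclass == "BND":
        chrom2, pos2 = _sample_position(rng, genome, gaps, 1)
    if vclass in CN_CLASSES:
        q = rng.uniform(*maf_range)
        m = int(np.clip(round(n * q), max(1, math.ceil(n * maf_range[0])), math.floor(n * maf_range[1])))
        cn = np.full(n, 2, dtype=float)
        carriers = rng.permutation(n)[:m]
        cn[carriers] = rng.choice([0, 1, 3, 4, 5, 6], size=m)
        dos = cn
    else:
        gt = _exact_genotypes(rng, n, *maf_range)
        dos = _ab_from_gt(rng, gt) if vclass in AB_CLASSES else gt.astype(float)
    return VariantRecord(
        id=vid, vclass=vclass, chrom=chrom, start=start, end=start + length,
        dosages=dos, chrom2=chrom2, pos2=pos2,
    )


_RARE_CLASSES = ["DEL", "DUP", "mCNV", "INV", "BND", "MEI"]


def _make_rare_sv(rng, idx, n, genome, gaps):
    vclass = _RARE_CLASSES[idx % len(_RARE_CLASSES)]
    length = _variant_length(rng, vclass)
    chrom, start = _sample_position(rng, genome, gaps, length)
    chrom2 = pos2 = None
    if vclass == "BND":
        chrom2, pos2 = _sample_position(rng, genome, gaps, 1)
    carrier = int(rng.integers(0, n))
    if vclass in CN_CLASSES:
        dos = np.full(n, 2, dtype=float)
        dos[carrier] = rng.choice([1, 3])
    elif vclass in AB_CLASSES:
        dos = np.zeros(n)
        dos[carrier] = round(float(np.clip(rng.normal(0.5, 0.05), 0.1, 1.0)), 6)
    else:
        dos = np.zeros(n)
        dos[carrier] = 1.0
    return VariantRecord(
        id=f"rSV_{idx:05d}", vclass=vclass, chrom=chrom, start=start,
        end=start + length, dosages=dos, chrom2=chrom2, pos2=pos2,
    ), carrier


def _relocate_near_genes(rng, variant, genes, coding, all_exons_by_chrom, genome):
    """Move ``variant`` so it sits in cis of every target gene; overlapping an
    exon of the first gene when ``coding`` and clear of all target-gene exons
    otherwise.  Dosages are untouched (position and dosage are independent)."""
    g0 = genes[0]
    length = max(variant.end - variant.start, 1)
    if coding:
        exon = min(g0.exons, key=lambda e: e.start)
        start = max(0, exon.start - length // 2)
        variant.chrom, variant.start, variant.end = g0.chrom, start, start + length
    else:
        target_exons = [e for g in genes for e in g.exons]
        for attempt in range(1000):
            offset = int(rng.integers(5_000, 200_000))
            start = g0.tss - offset - length if g0.strand == "+" else g0.tss + offset
            start = int(np.clip(start, 0, genome[g0.chrom] - length))
            probe = GenomicInterval(g0.chrom, start, start + length)
            if not any(overlaps(probe, e) for e in target_exons):
                variant.chrom, variant.start, variant.end = g0.chrom, start, start + length
                break
        else:
            raise ConfigError(f"could not place noncoding effect variant near {g0.gene_id}")
    for g in genes:
        if g.chrom != variant.chrom or variant.interval.distance_to_point(g.tss) > CIS_WINDOW:
            raise ConfigError(
                f"effect spec infeasible: {variant.id} cannot be in cis of all of "
                f"{[g.gene_id for g in genes]}"
            )


def _auto_plant_eqtls(rng, cfg, variants, genes, tissues):
    if cfg.n_eqtl_effects > len(variants):
        raise ConfigError("more effects than variants")
    sv_pool = np.array([i for i, v in enumerate(variants) if v.is_sv])
    pt_pool = np.array([i for i, v in enumerate(variants) if not v.is_sv])
    n_sv = min(int(round(cfg.eqtl_sv_fraction * cfg.n_eqtl_effects)), sv_pool.size)
    n_pt = min(cfg.n_eqtl_effects - n_sv, pt_pool.size)
    n_sv = min(cfg.n_eqtl_effects - n_pt, sv_pool.size)  # backfill if a pool ran short
    if n_sv + n_pt < cfg.n_eqtl_effects:
        raise ConfigError("more effects than variants")
    chosen = np.concatenate([
        rng.choice(sv_pool, size=n_sv, replace=False) if n_sv else np.array([], dtype=int),
        rng.choice(pt_pool, size=n_pt, replace=False) if n_pt else np.array([], dtype=int),
    ])
    genes_by_tss = sorted(genes, key=lambda g: (g.chrom, g.tss))
    used_genes: set[str] = set()
    effects = []
    for vi in chosen:
        v = variants[int(vi)]
        # pick an unused anchor gene, then neighbors for multi-gene effects
        order = rng.permutation(len(genes_by_tss))
        gi = next((int(j) for j in order if genes_by_tss[int(j)].gene_id not in used_genes), int(order[0]))
        k = 1
        if rng.random() < cfg.multi_gene_fraction:
            k = int(rng.integers(2, 4))
        targets = [genes_by_tss[gi]]
        j = gi
        while len(targets) < k and j + 1 < len(genes_by_tss):
            j += 1
            cand = genes_by_tss[j]
            if cand.chrom != targets[0].chrom:
                break
            if abs(cand.tss - targets[0].tss) > CIS_WINDOW // 2:
                break
            if cand.gene_id in used_genes:
                continue
            targets.append(cand)
        coding = bool(rng.random() < cfg.coding_fraction)
        tset = None
        if rng.random() < cfg.tissue_restricted_fraction:
            nt = int(rng.integers(1, max(2, cfg.n_tissues // 2 + 1)))
            tset = tuple(str(t) for t in sorted(rng.choice(tissues, size=nt, replace=False)))
        slope = cfg.effect_slope * float(rng.choice([-1, 1]))
        effects.append(
            EqtlEffect(
                variant_id=v.id,
                gene_ids=tuple(g.gene_id for g in targets),
                slope=slope,
                tissues=tset,
                coding=coding,
            )
        )
        used_genes.update(g.gene_id for g in targets)
    return effects


def _auto_plant_rare(rng, cfg, rare_variants, rare_carriers, genes):
    genes_by_tss = sorted(genes, key=lambda g: (g.chrom, g.tss))
    chosen = rng.choice(len(rare_variants), size=cfg.n_rare_outlier_effects, replace=False)
    effects = []
    used: set[str] = set()
    for vi in chosen:
        v = rare_variants[int(vi)]
        order = rng.permutation(len(genes_by_tss))
        gi = next((int(j) for j in order if genes_by_tss[int(j)].gene_id not in used), int(order[0]))
        k = 1
        if rng.random() < cfg.rare_regional_fraction:
            k = int(rng.integers(2, 4))
        targets = [genes_by_tss[gi]]
        j = gi
        while len(targets) < k and j + 1 < len(genes_by_tss):
            j += 1
            cand = genes_by_tss[j]
            if cand.chrom != targets[0].chrom or abs(cand.tss - targets[0].tss) > CIS_WINDOW // 2:
                break
            if cand.gene_id not in used:
                targets.append(cand)
        coding = bool(rng.random() < cfg.rare_coding_fraction)
        effects.append(
            RareOutlierEffect(
                variant_id=v.id,
                gene_ids=tuple(g.gene_id for g in targets),
                direction=int(rng.choice([-1, 1])),
                magnitude=cfg.outlier_magnitude,
                coding=coding,
            )
        )
        used.update(g.gene_id for g in targets)
    return effects


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full bundle deterministically from ``config.seed``."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    (ss_genes, ss_var, ss_rare, ss_cov, ss_fx, ss_expr) = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    samples = [f"sample_{i:04d}" for i in range(config.n_samples)]
    tissues = [f"tissue_{t + 1}" for t in range(config.n_tissues)]
    genome = {f"chr{k + 1}": config.chrom_length for k in range(config.n_chromosomes)}
    gaps = [
        GenomicInterval(c, (L - config.gap_length) // 2, (L + config.gap_length) // 2)
        for c, L in genome.items()
        if config.gap_length > 0
    ]

    # genes with exons
    genes: list[GeneModel] = []
    for i in range(config.n_genes):
        length = int(ss_genes.integers(5_000, 100_000))
        chrom, start = _sample_position(ss_genes, genome, gaps, length)
        strand = str(ss_genes.choice(["+", "-"]))
        n_ex = int(ss_genes.integers(2, 6))
        block = length // n_ex
        exons = []
        for b in range(n_ex):
            ex_len = int(min(ss_genes.integers(100, 400), block))
            ex_start = start + b * block
            exons.append(GenomicInterval(chrom, ex_start, ex_start + ex_len))
        genes.append(GeneModel(f"gene_{i:05d}", chrom, start, start + length, strand, exons))

    # common variants
    variants: list[VariantRecord] = []
    for vclass, count in config.class_counts.items():
        for i in range(count):
            variants.append(
                _make_common_variant(
                    ss_var, vclass, i, config.n_samples, genome, gaps, config.maf_range
                )
            )

    # rare singleton SVs
    n_rare = config.n_rare_svs
    if config.rare_effects:
        n_rare = max(n_rare, len(config.rare_effects))
    rare_variants: list[VariantRecord] = []
    rare_carriers: list[int] = []
    for i in range(n_rare):
        v, carrier = _make_rare_sv(ss_rare, i, config.n_samples, genome, gaps)
        rare_variants.append(v)
        rare_carriers.append(carrier)

    by_id = {v.id: v for v in variants + rare_variants}
    genes_by_id = {g.gene_id: g for g in genes}

    # planted eQTL effects
    if config.eqtl_effects is not None:
        eqtl_effects = list(config.eqtl_effects)
    else:
        eqtl_effects = _auto_plant_eqtls(ss_fx, config, variants, genes, tissues)
    for fx in eqtl_effects:
        if fx.variant_id not in by_id:
            raise ConfigError(f"effect references unknown variant {fx.variant_id}")
        targets = []
        for gid in fx.gene_ids:
            if gid not in genes_by_id:
                raise ConfigError(f"effect references unknown gene {gid}")
            targets.append(genes_by_id[gid])
        _relocate_near_genes(ss_fx, by_id[fx.variant_id], targets, fx.coding, None, genome)

    # planted rare outlier effects
    if config.rare_effects is not None:
        rare_effects = list(config.rare_effects)
    else:
        rare_effects = _auto_plant_rare(ss_fx, config, rare_variants, rare_carriers, genes) \
            if config.n_rare_outlier_effects else []
    planted_outliers: list[PlantedOutlier] = []
    for fx in rare_effects:
        if fx.variant_id not in by_id:
            raise ConfigError(f"rare effect references unknown variant {fx.variant_id}")
        v = by_id[fx.variant_id]
        carrier_mask = v.carriers()
        if carrier_mask.sum() != 1:
            raise ConfigError(f"rare effect variant {fx.variant_id} is not a singleton")
        targets = [genes_by_id[g] for g in fx.gene_ids]
        _relocate_near_genes(ss_fx, v, targets, fx.coding, None, genome)
        planted_outliers.append(
            PlantedOutlier(
                variant_id=fx.variant_id,
                sample_id=samples[int(np.flatnonzero(carrier_mask)[0])],
                gene_ids=fx.gene_ids,
                direction=fx.direction,
                coding=fx.coding,
            )
        )

    # covariates and loadings
    cov = ss_cov.normal(0, 1, size=(config.n_samples, config.n_covariates))
    covariates = pd.DataFrame(
        cov, index=samples, columns=[f"cov_{j + 1}" for j in range(config.n_covariates)]
    )
    baselines = ss_cov.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)

    # expression
    fx_by_gene: dict[str, list[EqtlEffect]] = {}
    for fx in eqtl_effects:
        for gid in fx.gene_ids:
            fx_by_gene.setdefault(gid, []).append(fx)
    rare_by_gene: dict[str, list[tuple[RareOutlierEffect, int]]] = {}
    for fx, po in zip(rare_effects, planted_outliers):
        ci = samples.index(po.sample_id)
        for gid in fx.gene_ids:
            rare_by_gene.setdefault(gid, []).append((fx, ci))

    panels: dict[str, ExpressionPanel] = {}
    gene_ids = [g.gene_id for g in genes]
    for t in tissues:
        loadings = ss_expr.normal(0, 0.5, size=(config.n_genes, config.n_covariates))
        noise = ss_expr.normal(0, config.noise_sd, size=(config.n_genes, config.n_samples))
        Y = baselines[:, None] + loadings @ cov.T + noise
        for gi, gid in enumerate(gene_ids):
            for fx in fx_by_gene.get(gid, ()):
                if fx.tissues is None or t in fx.tissues:
                    Y[gi] += fx.slope * by_id[fx.variant_id].dosages
            for fx, ci in rare_by_gene.get(gid, ()):
                Y[gi, ci] += fx.direction * fx.magnitude * config.noise_sd
        if config.floor_at_zero:
            Y = np.maximum(Y, 0.0)
        panels[t] = ExpressionPanel(
            tissue=t, values=pd.DataFrame(Y, index=gene_ids, columns=samples)
        )

    functional = sorted(
        {fx.variant_id for fx in eqtl_effects if by_id[fx.variant_id].is_sv}
    )
    truth = TruthTable(
        eqtls=eqtl_effects, outliers=planted_outliers, functional_sv_ids=functional
    )
    return Cohort(
        sample_ids=samples,
        tissues=tissues,
        genome=genome,
        gaps=gaps,
        genes=genes,
        variants=variants + rare_variants,
        panels=panels,
        covariates=covariates,
        truth=truth,
        config=config,
    )


def generate_feature_tracks(
    cohort: Cohort,
    enrichment_factor: float,
    seed: int = 0,
    n_tracks: int = 3,
    n_intervals: int = 200,
    interval_length: int = 500,
    neighborhood: int = 1_000,
) -> dict[str, list[GenomicInterval]]:
    """Named BED-style annotation tracks, uniform over the genome except
    enriched (by ``enrichment_factor``) within ``neighborhood`` bp of the
    truth table's functional SVs.  Factor 1 reduces to uniform placement;
    with no functional SVs the enriched placement is skipped entirely.
    """
    if enrichment_factor < 1:
        raise ConfigError("enrichment_factor must be >= 1")
    rng = np.random.default_rng(seed)
    functional = [
        cohort.variant(vid).interval for vid in cohort.truth.functional_sv_ids
    ]
    genome_bp = sum(cohort.genome.values())
    hoods = [
        GenomicInterval(iv.chrom, max(0, iv.start - neighborhood),
                        min(cohort.genome[iv.chrom], iv.end + neighborhood))
        for iv in functional
    ]
    q0 = sum(h.length for h in hoods) / genome_bp if hoods else 0.0
    q = min(0.9, enrichment_factor * q0)
    tracks: dict[str, list[GenomicInterval]] = {}
    for ti in range(n_tracks):
        ivs = []
        for _ in range(n_intervals):
            if hoods and rng.random() < q:
                h = hoods[int(rng.integers(0, len(hoods)))]
                lo = max(0, h.start - interval_length + 1)
                hi = min(cohort.genome[h.chrom] - interval_length, h.end - 1)
                start = int(rng.integers(lo, max(lo + 1, hi + 1)))
                chrom = h.chrom
            else:
                chrom, start = _sample_position(
                    rng, cohort.genome, cohort.gaps, interval_length
                )
            ivs.append(GenomicInterval(chrom, start, start + interval_length))
        tracks[f"track_{ti + 1}"] = ivs
    return tracks
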