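"""Readers and writers for the formats the pipeline touches.

Variant calls travel as a minimal VCF 4.2 dialect: INFO carries SVTYPE, END
and AF (plus CHR2/END2 for breakends); the per-sample dosage is FORMAT AB
(allele balance in [0,1]) for DEL/DUP/INV/BND, FORMAT CN (integer copy
number) for multiallelic CNVs and FORMAT GT for SNVs, indels and mobile
element insertions (genotypes 0/0, 0/1, 1/1 read as dosages 0, 1, 2).
Gene models are a BED12-like TSV, expression a genes x samples TSV per
tissue.  Readers tolerate gzip.  Coordinates are converted to 0-based
half-open on read (a record at POS 100 with END 200 becomes [99, 200)).
"""

from __future__ import annotations

import gzip
import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .intervals import GenomicInterval, to_zero_based

__all__ = [
    "VariantRecord",
    "GeneModel",
    "ExpressionPanel",
    "FormatError",
    "AB_CLASSES",
    "CN_CLASSES",
    "GT_CLASSES",
    "SV_CLASSES",
    "VARIANT_CLASSES",
    "read_variants",
    "write_variants",
    "read_gene_models",
    "write_gene_models",
    "read_expression",
    "write_expression",
    "read_covariates",
    "write_covariates",
    "read_bed",
    "write_bed",
]

AB_CLASSES = frozenset({"DEL", "DUP", "INV", "BND"})
CN_CLASSES = frozenset({"mCNV"})
GT_CLASSES = frozenset({"SNV", "INDEL", "MEI"})
SV_CLASSES = frozenset({"DEL", "DUP", "mCNV", "INV", "BND", "MEI"})
VARIANT_CLASSES = AB_CLASSES | CN_CLASSES | GT_CLASSES


class FormatError(ValueError):
    """A file is missing a required key or has a malformed record."""


@dataclass
class VariantRecord:
    """One variant with its per-sample dosage vector.

    The dosage encoding follows the variant class: allele balance in [0, 1]
    for breakpoint-genotyped SVs, integer copy number for mCNVs (cohort mode
    normally 2) and allele count 0/1/2 for point variants and MEIs.  BNDs
    carry two breakpoints and no defined length.
    """

    id: str
    vclass: str
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    dosages: np.ndarray
    chrom2: str | None = None
    pos2: int | None = None
    ref: str = "N"
    alt: str | None = None

    def __post_init__(self) -> None:
        if self.vclass not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.vclass!r}")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.vclass == "BND" and (self.chrom2 is None or self.pos2 is None):
            raise ValueError(f"BND {self.id} needs a mate breakpoint")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, name=self.id)

    @property
    def intervals(self) -> list[GenomicInterval]:
        """Both breakpoints for a BND; the single span otherwise."""
        if self.vclass == "BND":
            return [
                GenomicInterval(self.chrom, self.start, self.start + 1, name=self.id),
                GenomicInterval(self.chrom2, self.pos2, self.pos2 + 1, name=self.id),
            ]
        return [self.interval]

    @property
    def size(self) -> int | None:
        """Length in bp; None for BNDs (undefined by convention)."""
        if self.vclass == "BND":
            return None
        return self.end - self.start

    @property
    def is_sv(self) -> bool:
        return self.vclass in SV_CLASSES

    @property
    def cn_mode(self) -> int | None:
        if self.vclass not in CN_CLASSES:
            return None
        vals, counts = np.unique(self.dosages[~np.isnan(self.dosages)], return_counts=True)
        return int(vals[np.argmax(counts)])

    def carriers(self, ab_threshold: float = 0.0) -> np.ndarray:
        """Boolean carrier mask: nonzero dosage ("positively genotyped"),
        except mCNVs where a carrier deviates from the cohort modal copy
        number.  ``ab_threshold`` raises the allele-balance cutoff."""
        d = self.dosages
        if self.vclass in CN_CLASSES:
            return (d != self.cn_mode) & ~np.isnan(d)
        if self.vclass in AB_CLASSES:
            return d > ab_threshold
        return d > 0

    @property
    def af(self) -> float:
        """Alternate-allele (or non-modal-copy) frequency."""
        d = self.dosages[~np.isnan(self.dosages)]
        if self.vclass in GT_CLASSES:
            return float(np.mean(d) / 2.0)
        if self.vclass in CN_CLASSES:
            return float(np.mean(d != self.cn_mode))
        return float(np.mean(d))  # allele balance approximates allele frequency

    @property
    def maf(self) -> float:
        return float(min(self.af, 1.0 - self.af))


@dataclass
class GeneModel:
    """A gene with strand, exons and a strand-determined TSS."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        for ex in self.exons:
            if ex.start < self.start or ex.end > self.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene body")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, strand=self.strand, name=self.gene_id)


@dataclass
class ExpressionPanel:
    """Per-tissue genes x samples expression matrix (NaN marks missing)."""

    tissue: str
    values: pd.DataFrame  # index: gene ids, columns: sample ids

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# VCF

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Variant class">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position (1-based inclusive)">
##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">
##INFO=<ID=CHR2,Number=1,Type=String,Description="Mate chromosome (BND)">
##INFO=<ID=END2,Number=1,Type=Integer,Description="Mate position, 1-based (BND)">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AB,Number=1,Type=Float,Description="Allele balance dosage">
##FORMAT=<ID=CN,Number=1,Type=Integer,Description="Copy number">
"""


def write_variants(
    variants: list[VariantRecord], sample_ids: list[str], path: str | Path,
    contigs: dict[str, int] | None = None,
) -> None:
    """Write the minimal VCF 4.2 dialect described in the module docstring."""
    path = Path(path)
    lines = [_VCF_HEADER.rstrip("\n")]
    if contigs:
        for c, ln in contigs.items():
            lines.append(f"##contig=<ID={c},length={ln}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids))
    for v in sorted(variants, key=lambda x: (x.chrom, x.start, x.id)):
        pos = v.start + 1
        alt = v.alt if v.alt else f"<{v.vclass}>"
        info = f"SVTYPE={v.vclass};END={v.end};AF={v.af:.6g}"
        if v.vclass == "BND":
            info += f";CHR2={v.chrom2};END2={v.pos2 + 1}"
        if v.vclass in AB_CLASSES:
            fmt, cells = "AB", [f"{d:.6g}" for d in v.dosages]
        elif v.vclass in CN_CLASSES:
            fmt, cells = "CN", [str(int(d)) for d in v.dosages]
        else:
            gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
            fmt, cells = "GT", [gt_map[int(d)] for d in v.dosages]
        lines.append(
            f"{v.chrom}\t{pos}\t{v.id}\t{v.ref}\t{alt}\t.\tPASS\t{info}\t{fmt}\t" + "\t".join(cells)
        )
    path.write_text("\n".join(lines) + "\n")


def read_variants(path: str | Path) -> list[VariantRecord]:
    """Read variants, converting coordinates to 0-based half-open and
    applying the per-class dosage encoding.  Missing required keys raise
    :class:`FormatError` naming the key and record."""
    out: list[VariantRecord] = []
    vcf = VCF(str(path))
    try:
        for i, rec in enumerate(vcf, start=1):
            vclass = rec.INFO.get("SVTYPE")
            if vclass is None:
                raise FormatError(f"record {i} ({rec.CHROM}:{rec.POS}): missing INFO key SVTYPE")
            if vclass not in VARIANT_CLASSES:
                raise FormatError(f"record {i}: unknown SVTYPE {vclass!r}")
            end_1based = rec.INFO.get("END")
            if end_1based is None:
                raise FormatError(f"record {i} ({rec.ID}): missing INFO key END")
            start, end = to_zero_based(rec.POS, int(end_1based))
            chrom2 = pos2 = None
            if vclass == "BND":
                chrom2 = rec.INFO.get("CHR2")
                end2 = rec.INFO.get("END2")
                if chrom2 is None or end2 is None:
                    raise FormatError(f"record {i} ({rec.ID}): BND missing INFO key CHR2/END2")
                pos2 = int(end2) - 1
            if vclass in AB_CLASSES:
                raw = rec.format("AB")
                if raw is None:
                    raise FormatError(f"record {i} ({rec.ID}): missing FORMAT key AB")
                dos = raw[:, 0].astype(float)
            elif vclass in CN_CLASSES:
                raw = rec.format("CN")
                if raw is None:
                    raise FormatError(f"record {i} ({rec.ID}): missing FORMAT key CN")
                dos = raw[:, 0].astype(float)
            else:
                gts = rec.genotype.array()
                if gts is None:
                    raise FormatError(f"record {i} ({rec.ID}): missing FORMAT key GT")
                alleles = gts[:, :2].astype(float)
                alleles[alleles < 0] = np.nan
                dos = alleles.sum(axis=1)
            out.append(
                VariantRecord(
                    id=rec.ID or f"var_{i}",
                    vclass=vclass,
                    chrom=rec.CHROM,
                    start=start,
                    end=end,
                    dosages=dos,
                    chrom2=chrom2,
                    pos2=pos2,
                )
            )
    finally:
        vcf.close()
    return out


# ---------------------------------------------------------------------------
# gene models (BED12-like TSV, 0-based half-open like BED)


def write_gene_models(genes: list[GeneModel], path: str | Path) -> None:
    rows = []
    for g in genes:
        exons = sorted(g.exons, key=lambda e: e.start)
        sizes = ",".join(str(e.length) for e in exons)
        starts = ",".join(str(e.start - g.start) for e in exons)
        rows.append(
            f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
            f"{g.start}\t{g.end}\t0\t{len(exons)}\t{sizes}\t{starts}"
        )
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"line {lineno}: expected 12 BED12 fields, got {len(f)}")
            chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            n_exons = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")][:n_exons]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")][:n_exons]
            exons = [
                GenomicInterval(chrom, start + off, start + off + sz)
                for off, sz in zip(offsets, sizes)
            ]
            genes.append(GeneModel(name, chrom, start, end, strand, exons))
    return genes


# ---------------------------------------------------------------------------
# expression / covariates / BED


def write_expression(panel: ExpressionPanel, path: str | Path) -> None:
    panel.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6f")


def read_expression(path: str | Path, tissue: str) -> ExpressionPanel:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return ExpressionPanel(tissue=tissue, values=df)


def write_covariates(cov: pd.DataFrame, path: str | Path) -> None:
    cov.to_csv(path, sep="\t", index_label="sample_id", float_format="%.6f")


def read_covariates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    rows = [
        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}"
        for iv in intervals
    ]
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 and f[3] != "." else None
            strand = f[5] if len(f) > 5 and f[5] in "+-" else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand=strand, name=name))
    return out
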