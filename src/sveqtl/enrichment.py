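"""Enrichment of SV sets at annotation tracks.

Two null constructions are provided, mirroring how common and rare SV sets
are evaluated:

* shuffle-based — SVs (grouped, e.g. by causality bin) are placed at random
  into non-gapped sequence within 1 Mb of a TSS, optionally barred from
  exons, 100 times; fold = observed overlap count / median null count, with
  an empirical one-sided p and a 95% CI from the observed/null ratio
  percentiles;
* Fisher-based — outlier-associated vs control-associated SVs form a 2x2
  table per feature (two-sided Fisher exact test, Bonferroni-corrected).

Flanking rules: 1 kb around annotations by default; exons none; TSS/3' end
windows are 10 kb directional intervals built upstream; TAD boundaries 5 kb;
chromatin-state segments none.  SVs touching an exon of an associated eGene
are excluded from every feature except the eGene-exon feature itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genio import VariantRecord
from .intervals import GenomicInterval, overlaps, shuffle_intervals

__all__ = [
    "EnrichmentResult",
    "DEFAULT_FLANKS",
    "flank_for",
    "annotate_overlaps",
    "shuffle_enrichment",
    "fisher_enrichment",
]

DEFAULT_FLANKS = {
    "default": 1_000,
    "enhancer": 1_000,
    "exon": 0,
    "tss_window": 0,      # already a 10-kb directional window
    "end3_window": 0,     # already a 10-kb directional window
    "tad_boundary": 5_000,
    "chromatin_state": 0,
}


_WARNED_FEATURES: set[str] = set()


def flank_for(feature_name: str, flanks: dict[str, int] | None = None) -> int:
    """Flank rule for a feature by name prefix; unknown features fall back to
    the 1-kb default with a warning (once per feature name)."""
    table = dict(DEFAULT_FLANKS)
    if flanks:
        table.update(flanks)
    for key in table:
        if key != "default" and feature_name.startswith(key):
            return table[key]
    if feature_name not in table and feature_name not in _WARNED_FEATURES:
        _WARNED_FEATURES.add(feature_name)
        warnings.warn(
            f"unknown feature class {feature_name!r}; using default flank", stacklevel=2
        )
    return table.get(feature_name, table["default"])


@dataclass
class EnrichmentResult:
    feature: str
    group: str
    observed: int
    null_median: float
    fold: float
    ci_low: float
    ci_high: float
    p: float
    significant: bool | None = None


def _sv_hits_feature(spans: list[GenomicInterval], feature: list[GenomicInterval],
                     flank: int) -> bool:
    return any(overlaps(s, f, flank=flank) for s in spans for f in feature)


def annotate_overlaps(
    svs: list[VariantRecord],
    features: dict[str, list[GenomicInterval]],
    flanks: dict[str, int] | None = None,
    excluded_sv_ids: set[str] | frozenset[str] = frozenset(),
    exon_feature: str = "exon",
) -> pd.DataFrame:
    """Boolean SV x feature overlap matrix under the per-feature flank rules.

    SVs in ``excluded_sv_ids`` (those touching an exon of an associated
    eGene) count as non-overlapping for every feature except the exon
    feature."""
    mat = {}
    for name, feature in features.items():
        fl = flank_for(name, flanks)
        col = []
        for v in svs:
            if v.id in excluded_sv_ids and name != exon_feature:
                col.append(False)
            else:
                col.append(_sv_hits_feature(v.intervals, feature, fl))
        mat[name] = col
    return pd.DataFrame(mat, index=[v.id for v in svs])


def _count_overlaps(spans_list, feature, flank):
    return sum(_sv_hits_feature(spans, feature, flank) for spans in spans_list)


def shuffle_enrichment(
    svs_by_group: dict[str, list[VariantRecord]],
    features: dict[str, list[GenomicInterval]],
    genome: dict[str, int],
    gaps: list[GenomicInterval],
    tss_list: list[tuple[str, int]],
    exon_intervals: list[GenomicInterval] = (),
    flanks: dict[str, int] | None = None,
    n_shuffles: int = 100,
    seed: int = 0,
    max_tss_distance: int = 1_000_000,
    exon_feature: str = "exon",
    excluded_sv_ids: set[str] = frozenset(),
) -> list[EnrichmentResult]:
    """Shuffle-null enrichment per group x feature.

    Each group's SV intervals are re-placed ``n_shuffles`` times into
    non-gapped sequence within ``max_tss_distance`` of a TSS; placements may
    not intersect ``exon_intervals`` except when scoring the exon feature
    itself (for which unconstrained-by-exon shuffles are drawn separately).
    fold = observed / median(null); 95% CI from the 2.5-97.5 percentiles of
    observed/null ratios; empirical one-sided
    p = (1 + #{null >= observed}) / (n_shuffles + 1).
    """
    results: list[EnrichmentResult] = []
    ss = np.random.SeedSequence(seed)
    group_seeds = dict(zip(sorted(svs_by_group), ss.spawn(len(svs_by_group))))
    for group in sorted(svs_by_group):
        svs = svs_by_group[group]
        ivs = [iv for v in svs for iv in (
            [v.interval] if v.vclass != "BND" else v.intervals)]
        rng = np.random.default_rng(group_seeds[group])
        shuffled_noexon = shuffle_intervals(
            ivs, genome, gaps=gaps, tss_list=tss_list,
            max_tss_distance=max_tss_distance, forbidden=list(exon_intervals),
            n_shuffles=n_shuffles, seed=rng,
        )
        shuffled_free = shuffle_intervals(
            ivs, genome, gaps=gaps, tss_list=tss_list,
            max_tss_distance=max_tss_distance, forbidden=(),
            n_shuffles=n_shuffles, seed=rng,
        ) if exon_feature in features else None
        spans_by_sv = [v.intervals for v in svs]
        for name, feature in features.items():
            if not feature or sum(f.length for f in feature) == 0:
                warnings.warn(f"feature {name!r} has zero extent; skipped", stacklevel=2)
                continue
            fl = flank_for(name, flanks)
            if name == exon_feature:
                observed = sum(
                    _sv_hits_feature(spans, feature, fl) for spans in spans_by_sv
                )
                shuffles = shuffled_free
            else:
                observed = sum(
                    _sv_hits_feature(spans, feature, fl)
                    for v, spans in zip(svs, spans_by_sv)
                    if v.id not in excluded_sv_ids
                )
                shuffles = shuffled_noexon
            # group placed breakpoints back into SV units by name so a
            # two-breakpoint BND counts once, as in the observed tally
            def _units(placed):
                by_name: dict[str, list[GenomicInterval]] = {}
                for k, iv in enumerate(placed):
                    by_name.setdefault(iv.name or str(k), []).append(iv)
                return list(by_name.values())

            null = np.array(
                [_count_overlaps(_units(placed), feature, fl) for placed in shuffles],
                dtype=float,
            )
            null_med = float(np.median(null))
            fold = observed / null_med if null_med > 0 else (
                np.nan if observed == 0 else np.inf
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                ratios = observed / null
            finite = ratios[np.isfinite(ratios)]
            ci = tuple(np.percentile(finite, [2.5, 97.5])) if finite.size else (np.nan, np.nan)
            p = float((1 + np.sum(null >= observed)) / (n_shuffles + 1))
            results.append(
                EnrichmentResult(
                    feature=name, group=str(group), observed=int(observed),
                    null_median=null_med, fold=float(fold),
                    ci_low=float(ci[0]), ci_high=float(ci[1]), p=p,
                )
            )
    return results


def fisher_enrichment(
    group_a: list[VariantRecord],
    group_b: list[VariantRecord],
    features: dict[str, list[GenomicInterval]],
    flanks: dict[str, int] | None = None,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Two-sided Fisher exact enrichment of group a (e.g. noncoding
    outlier-associated SVs) versus group b (controls) per feature, Bonferroni
    corrected over the number of features.  fold is the overlap-rate ratio.
    """
    if not group_a or not group_b:
        raise ValueError("both SV groups must be non-empty")
    n_features = len(features)
    results = []
    for name, feature in features.items():
        fl = flank_for(name, flanks)
        a_yes = sum(_sv_hits_feature(v.intervals, feature, fl) for v in group_a)
        b_yes = sum(_sv_hits_feature(v.intervals, feature, fl) for v in group_b)
        a_no = len(group_a) - a_yes
        b_no = len(group_b) - b_yes
        p = float(stats.fisher_exact([[a_yes, a_no], [b_yes, b_no]],
                                     alternative="two-sided")[1])
        rate_a = a_yes / len(group_a)
        rate_b = b_yes / len(group_b)
        fold = rate_a / rate_b if rate_b > 0 else (np.nan if rate_a == 0 else np.inf)
        results.append(
            EnrichmentResult(
                feature=name, group="a_vs_b", observed=a_yes,
                null_median=float(b_yes), fold=float(fold),
                ci_low=np.nan, ci_high=np.nan, p=p,
                significant=bool(p * n_features < alpha),
            )
        )
    return results
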