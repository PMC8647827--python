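"""Causality scoring of cis-SVs and annotation enrichment by causality bin.

Each significant eGene's strongest cis-SV gets a score = (single-causal
fine-mapping posterior) x (share of cis heritability explained by the SV).
Unique SVs are split into six quantile bins (bin 1 = bottom half) and tested
for enrichment at annotation tracks against a constrained shuffle null.
"""

import numpy as np

from sveqtl import CohortConfig, generate_cohort, generate_feature_tracks
from sveqtl.enrichment import shuffle_enrichment
from sveqtl.pipeline import run_eqtl, score_causality

cfg = CohortConfig(n_samples=150, n_genes=150, n_tissues=2, seed=31,
                   n_eqtl_effects=30, eqtl_sv_fraction=0.3,
                   coding_fraction=0.0)
cohort = generate_cohort(cfg)
results, vm, resid = run_eqtl(cohort, n_perm=300, seed=2)
scores, excluded = score_causality(cohort, results, vm, resid)

planted = set(cohort.truth.functional_sv_ids)
print(f"scored SVs: {len(scores)}  (h2 estimation failed for {len(excluded)})")
for s in scores[:3]:
    flag = "planted" if s.sv_id in planted else "null"
    print(f"  {s.sv_id}: posterior {s.posterior:.2f} x h2-fraction "
          f"{s.h2_sv_fraction:.2f} = score {s.score:.2f} -> bin {s.bin} [{flag}]")
top_bins = [s.bin for s in scores if s.sv_id in planted]
print(f"planted causal SVs land in bins: {sorted(top_bins)} (6 = most causal)")

# Annotation tracks enriched 8-fold near the truly functional SVs
tracks = generate_feature_tracks(cohort, enrichment_factor=8.0, seed=9)
by_bin = {}
for s in scores:
    group = "top" if s.bin >= 5 else "bottom"
    by_bin.setdefault(group, []).append(cohort.variant(s.sv_id))
res = shuffle_enrichment(
    by_bin, {"enhancer_track": tracks["track_1"]},
    cohort.genome, cohort.gaps,
    tss_list=[(g.chrom, g.tss) for g in cohort.genes],
    exon_intervals=[e for g in cohort.genes for e in g.exons],
    n_shuffles=100, seed=4,
)
print("\nshuffle-null enrichment at the planted-enriched track:")
for r in res:
    print(f"  {r.group}-bin SVs: fold {r.fold:.2f} "
          f"(95% CI {r.ci_low:.2f}-{r.ci_high:.2f}), empirical p {r.p:.3f}")
# The top causality bin should show the higher fold: the track was placed
# preferentially near the variants that truly drive expression.
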