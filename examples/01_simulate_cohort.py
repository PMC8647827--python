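"""Generate a synthetic multi-tissue cohort and write the bundle to disk.

The generator plants known cis-eQTL effects (common variants) and rare
singleton-SV expression-outlier effects, and records them in a truth table
so every downstream claim can be checked against ground truth.
"""

import tempfile
from pathlib import Path

from sveqtl import CohortConfig, generate_cohort

cfg = CohortConfig(
    n_samples=120,
    n_tissues=3,
    n_genes=150,
    n_eqtl_effects=10,      # planted common cis effects (half on SVs)
    n_rare_svs=25,          # singleton SVs, one carrier each
    n_rare_outlier_effects=10,
    seed=11,
)
cohort = generate_cohort(cfg)

outdir = Path(tempfile.mkdtemp()) / "cohort"
cohort.write(outdir)

n_common = sum(1 for v in cohort.variants if not v.id.startswith("r"))
n_sv = sum(1 for v in cohort.variants if v.is_sv)
print(f"samples: {len(cohort.sample_ids)}  tissues: {len(cohort.tissues)}  "
      f"genes: {len(cohort.genes)}")
print(f"variants: {len(cohort.variants)} ({n_common} common, "
      f"{len(cohort.variants) - n_common} rare; {n_sv} SVs)")
print(f"planted eQTL effects: {len(cohort.truth.eqtls)}  "
      f"planted outlier effects: {len(cohort.truth.outliers)}")
print(f"bundle written to {outdir} "
      f"({', '.join(sorted(p.name for p in outdir.iterdir()))})")
# The truth table lists which variant drives which gene(s): downstream
# analyses are scored against exactly these plantings.
fx = cohort.truth.eqtls[0]
print(f"example planted effect: {fx.variant_id} -> {fx.gene_ids} "
      f"slope {fx.slope:+.1f} tissues {fx.tissues or 'all'}")
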