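# Methods

This note documents the models, parameter choices and numerical decisions
behind `sveqtl`, and what the synthetic-data results do and do not show.

## Synthetic cohort

The generator emulates the data structure of a WGS + multi-tissue RNA-seq
cohort on a toy genome (default 2 chromosomes × 25 Mb, one central 500-kb
assembly gap each, so shuffle engines must respect non-gapped space).

*Variants.*  Eight classes with the dosage encodings used downstream:
allele balance in [0, 1] for DEL/DUP/INV/BND (heterozygotes ~0.5 with
centred noise, homozygotes 1.0 — read-evidence genotyping is noisy in
exactly this way), integer copy number 0–6 with cohort mode 2 for mCNVs,
and allele counts 0/1/2 for SNVs, indels and MEIs.  Allele counts are
assigned by permutation so realized allele frequencies fall exactly inside
the configured MAF range (default [0.01, 0.5]); the default catalog is 3000
common variants (300 SVs, 2400 SNVs, 300 indels) — SV share and class mix
roughly follow the relative abundances seen in joint call sets.  BNDs carry
two breakpoints and no defined length; a BND is "in" a window if either
breakpoint is.  Rare SVs have exactly one carrier.

*Expression.*  For gene g, tissue t, sample s:

    y = baseline_g + covariates_s · loadings_{g,t}
        + Σ planted slopes × dosage + N(0, noise_sd)

on a continuous scale that stands for PEER-corrected expression; the
explicit covariates stand in for PEER factors and are residualized out by
the analysis (including before outlier Z-scoring — Z-scores of
PEER-corrected values presuppose the correction).  Defaults: noise_sd 1.0
(so planted slopes are in noise-sd units), 3 covariates with N(0, 0.5)
loadings, planted eQTL slope 3.0 — a strong but realistic large-effect
cis-eQTL at the default n = 200.  Rare outlier effects shift the carrier by
direction × magnitude × noise_sd (default 6) in all tissues.  An optional
`floor_at_zero` mode clips expression at zero, reproducing the detection
asymmetry between over- and under-expression outliers.

*Determinism.*  One global seed expands through
`numpy.random.SeedSequence(seed).spawn()` into independent child streams
(genes, variants, rare variants, covariates, effects, expression), so the
written bundle is byte-identical across runs with the same seed.

*What the generator does not emulate:* linkage disequilibrium (variants are
independent), population structure, read-level noise, library-size or
count-distribution effects, and real annotation biology.  Passing tests
therefore demonstrate the correctness and calibration of the machinery, not
discovery performance on real cohorts — with LD absent, fine-mapping and
lead-marker assignment are easier than in real data.

## eQTL mapping

Nominal association is simple linear regression on residualized expression
with a two-sided t test; because covariates are removed beforehand, df =
n − 2.  Missing dosages are dropped pairwise for reported statistics and
mean-imputed only inside the vectorized permutation pass.  The cis window
is ±1 Mb of the TSS, MAF ≥ 0.01, all classes pooled so they compete for
lead status.  Lead ties (e.g. perfect LD) break by smallest p, then largest
|slope|, then leftmost position, then lexicographic id.

Permutations shuffle expression across samples jointly against all cis
variants; the default is a fixed 1000 permutations (reproducibility over
speed), with optional adaptive early stopping once 100 null leads beat the
observed one.  The beta null fit is a maximum-likelihood Beta(a, b) via
moment initialization and Newton iterations on the digamma score equations;
a degenerate (all-equal) null falls back to the rank p with a warning.  The
empirical p is the beta CDF at the observed lead p; across observed values
in [0.001, 0.5] it tracks the direct permutation rank p within 0.01 at
10,000 permutations (asserted).  Test suites use 150–300 permutations per
gene, the size at which the beta fit is already stable (≥ 50 nulls needed)
and a 20-replicate null calibration finishes in ~1.5 minutes.

## Causality score

The fine-mapping posterior uses the single-causal-variant approximation:
marginal Wakefield log Bayes factors from the z-scores with a
N(0, prior_effect_sd²) prior on the standardized effect, prior_effect_sd
default 0.5, with K_i = (prior_sd/se_i)² when standard errors are supplied
(the pipeline supplies se ≈ √((1−r²)/df), so the prior is scaled to the
sampling precision) and K = prior_sd² on the bare z scale otherwise.
An LD matrix argument is accepted and validated (ridge 1e-3 on the
diagonal) but does not enter the marginal BFs; the score needs a relative
ranking, not a credible set.  Cis h² is Haseman–Elston regression —
unbiased at desk scale, no iterative REML — of y_i y_j (standardized) on
the off-diagonal GRM entries, clipped to [0, 1]; genes where it fails (n <
50, degenerate GRM) are excluded from enrichment, mirroring how loci
without usable heritability estimates are dropped.  Binning: one score per
unique SV (max over its gene/tissue pairs); bin 1 = scores ≤ median, bins
2–6 the successive deciles of the upper half, ties to the lower bin; fewer
than 12 SVs trigger a coarse 2-bin split with a warning.

## Feature enrichment

Flank rules: 1 kb default around annotations, exons 0, 10-kb directional
TSS/3′ windows are explicit intervals (no extra flank), TAD boundaries
5 kb, chromatin-state segments 0; a no-padding sensitivity mode is just a
flank override.  SVs touching an exon of an associated eGene are excluded
from every feature except the exon feature itself.  The shuffle null
re-places each bin's intervals uniformly (rejection sampling, 10,000
attempts then a loud error) into non-gapped sequence within 1 Mb of a TSS
and outside all exons — the exon-feature run draws its own
exon-unconstrained shuffles.  With 100 shuffles: fold = observed / median
null, the 95% CI is the 2.5–97.5 percentile band of observed/null ratios
(the CI-on-ratios reading; counts vs folds is unstated in the field and
documented here as our choice), and the one-sided empirical
p = (1 + #{null ≥ obs}) / (n + 1), so p ∈ [1/(n+1), 1].  The
outlier-vs-control comparison uses a two-sided Fisher exact test with
Bonferroni correction over the feature count.

## Cross-tissue m-values

Likelihood: inactive tissues β_t ~ N(0, se_t²); active tissues share μ with
prior N(0, prior_effect_sd²), integrated in closed form.  Priors —
P(active) = 0.5 per tissue, effect sd 0.3 on the β scale — are configurable
defaults, not published values.  Exact enumeration up to T = 14 (16k
configurations, vectorized); beyond that, Metropolis MCMC (default 100,000
iterations, 10,000 burn-in).  The posterior over configurations is sharply
multimodal and sign-coherent (active tissues must share one μ), so the
sampler mixes single-tissue flips (90%), double flips (5%) and
Metropolis–Hastings independence draws (5%) from a two-component mixture of
per-tissue product distributions favouring the positive- and negative-effect
tissue sets; burn-in anneals the target and the chain starts from the
marginal evidence (|β/se| > 2).  Split-chain disagreement > 0.05 flags
non-convergence.  Agreement with exact enumeration at T = 10 is within 0.03
per tissue (asserted).  One modelling consequence worth knowing: a fully
null profile is *ambiguous*, not inactive — the all-active configuration
with μ ≈ 0 pays its Occam penalty only once, so m ≈ 0.4 everywhere;
inactivity is only decidable once other tissues pin a nonzero effect.

## Outliers and rare SVs

Z-scores use the sample standard deviation (n − 1); the four class rules
are applied independently (a pair can be multitissue and tissue-restricted
at once; control excludes all outlier classes by construction).  Gene/sample
pairs need data in ≥ 5 tissues.  The excess-outlier sample filter (count >
Q3 + 3·IQR of per-sample counts) is our operationalization of a cohort-level
manual exclusion.  "Positively genotyped" means dosage > 0 (configurable
allele-balance threshold); mCNV carriers deviate from the modal copy number.
Singletons larger than 1 Mb are dropped; BNDs, size-undefined, stay (and are
excluded from size-based odds ratios).  Upstream/downstream labels are
strand-aware distances from the gene-body edge.  The enrichment null
permutes outlier sample names as a bijection of the sample universe, which
preserves the total and per-gene outlier counts exactly; the regional-burden
null instead shuffles carrier labels across the associated-SV set, matching
the label-permutation design of that analysis.  Woolf CIs on log OR;
Haldane–Anscombe 0.5 on zero cells, flagged.

## Interfaces and shape

The package is a library plus narrative `examples/`; the per-stage
functions and `scripts/acceptance.py` are the operational interface, and no
console CLI is shipped — the expected user drives these analyses from
Python, not a shell.  On-disk formats are a minimal VCF 4.2 dialect (INFO
SVTYPE/END/AF, CHR2/END2 for breakends; FORMAT AB, CN or GT by class; read
through cyvcf2, gzip tolerated), BED12-like gene models, and per-tissue
genes × samples TSV expression.  Coordinates are 0-based half-open
internally, converted at the I/O boundary; interval overlap is strict
half-open (boundary touching is not overlap — the field leaves this
unstated, so it is pinned here and in tests).

## Known limitations

No LD and no multi-causal fine-mapping (single-causal posteriors are a
ranking device); no conditional or trans eQTLs; HE regression is less
efficient than REML at small n; the MCMC convergence diagnostic can miss
symmetric multimodality; synthetic annotation tracks are geometric, not
biological; and all power/recovery numbers quoted by the tests are
properties of the synthetic study conditions stated above, not of any real
cohort.
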