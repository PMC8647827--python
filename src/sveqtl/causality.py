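"""Causality scoring for the strongest cis-SV of each eGene.

The score is the product of two quantities in [0, 1]:

* a single-causal-variant fine-mapping posterior — per-variant approximate
  Bayes factors from the marginal z-scores with a N(0, prior_effect_sd^2)
  prior on the standardized effect, normalized over the cis region;
* the fraction of cis heritability attributed to the SV — cis h2 from
  Haseman–Elston regression of expression cross-products on the cis
  genetic-relatedness matrix, with the SV's univariate variance explained
  divided by that h2 (capped at 1).

Scored SVs are deduplicated to their best gene/tissue pair and allocated to
six quantile bins: bin 1 holds the bottom 50% of scores, bins 2-6 the
successive deciles of the top half (ties go to the lower bin).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genio import VariantRecord

__all__ = [
    "CausalityScore",
    "finemap_posterior",
    "cis_h2",
    "sv_h2_fraction",
    "select_and_bin",
]


@dataclass
class CausalityScore:
    sv_id: str
    gene_id: str
    tissue: str
    posterior: float
    h2_cis: float
    h2_sv_fraction: float
    score: float
    bin: int | None = None


def finemap_posterior(
    z_scores: np.ndarray,
    corr: np.ndarray | None = None,
    prior_effect_sd: float = 0.5,
    ridge: float = 1e-3,
    ses: np.ndarray | None = None,
) -> np.ndarray:
    """Posterior probability of causality per cis variant under a
    single-causal-variant model.

    Wakefield-style approximate Bayes factors from the marginal z-scores
    with a N(0, prior_effect_sd^2) prior on the standardized effect:
    log BF_i = 0.5 log(1/(1+K_i)) + 0.5 z_i^2 K_i/(1+K_i), where
    K_i = (prior_effect_sd / se_i)^2 when the effect standard errors are
    supplied (se ~ 1/sqrt(n) on the standardized scale) and
    K_i = prior_effect_sd^2 otherwise.  Posteriors are the normalized BFs
    and sum to 1.  The dosage correlation matrix, when given, is
    ridge-regularized and validated positive semidefinite; the marginal BFs
    themselves depend only on the z-scores.
    """
    z = np.asarray(z_scores, dtype=float)
    if z.size == 0:
        raise ValueError("need at least one variant")
    if corr is not None:
        R = np.asarray(corr, dtype=float)
        R = 0.5 * (R + R.T) + ridge * np.eye(R.shape[0])
        if np.linalg.eigvalsh(R).min() < -1e-8:
            raise ValueError("correlation matrix not PSD after ridge regularization")
    if ses is not None:
        se = np.asarray(ses, dtype=float)
        if np.any(se <= 0):
            raise ValueError("standard errors must be positive")
        K = (prior_effect_sd / se) ** 2
    else:
        K = np.full(z.shape, prior_effect_sd**2)
    logbf = 0.5 * np.log(1.0 / (1.0 + K)) + 0.5 * z**2 * K / (1.0 + K)
    if not np.all(np.isfinite(logbf)):
        warnings.warn("non-finite Bayes factors; returning uniform posterior", stacklevel=2)
        return np.full(z.size, 1.0 / z.size)
    logbf = logbf - logbf.max()
    bf = np.exp(logbf)
    return bf / bf.sum()


def cis_h2(expression_residuals: np.ndarray, cis_dosages: np.ndarray) -> float:
    """Cis heritability by Haseman–Elston regression.

    ``cis_dosages`` is variants x samples.  Dosages are standardized into the
    genetic-relatedness matrix A = Z'Z/m; the HE estimator regresses the
    off-diagonal products y_i y_j of standardized expression on A_ij.
    The estimate is clipped to [0, 1].  Requires n >= 50 samples.
    """
    y = np.asarray(expression_residuals, dtype=float)
    D = np.atleast_2d(np.asarray(cis_dosages, dtype=float))
    n = y.size
    if n < 50:
        raise ValueError("Haseman–Elston regression needs n >= 50 samples")
    if D.shape[1] != n:
        raise ValueError("dosage matrix must be variants x samples")
    sd_y = y.std()
    if sd_y == 0:
        warnings.warn("constant expression; h2 = 0", stacklevel=2)
        return 0.0
    ys = (y - y.mean()) / sd_y
    sds = D.std(axis=1)
    keep = sds > 0
    if not keep.any():
        warnings.warn("all cis dosages constant; h2 = 0", stacklevel=2)
        return 0.0
    Z = (D[keep] - D[keep].mean(axis=1, keepdims=True)) / sds[keep, None]
    m = Z.shape[0]
    A = (Z.T @ Z) / m
    iu = np.triu_indices(n, k=1)
    a = A[iu]
    prod = np.outer(ys, ys)[iu]
    denom = float(a @ a)
    if denom == 0:
        warnings.warn("degenerate relatedness matrix; h2 = 0", stacklevel=2)
        return 0.0
    h2 = float(a @ prod) / denom
    return float(np.clip(h2, 0.0, 1.0))


def sv_h2_fraction(
    sv_dosage: np.ndarray, expression_residuals: np.ndarray, h2_cis: float
) -> float:
    """min(1, R2_sv / h2_cis): the share of cis heritability attributable to
    the SV's univariate variance explained; 0 by convention when h2_cis = 0."""
    if h2_cis < 0:
        raise ValueError("h2_cis must be non-negative")
    if h2_cis == 0:
        return 0.0
    x = np.asarray(sv_dosage, dtype=float)
    y = np.asarray(expression_residuals, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(min(1.0, r * r / h2_cis))


def select_and_bin(scores: list[CausalityScore]) -> list[CausalityScore]:
    """One score per unique SV (its max over gene/tissue pairs), allocated to
    six quantile bins; with fewer than 12 SVs a coarser two-bin split around
    the median is used (with a warning)."""
    best: dict[str, CausalityScore] = {}
    for s in sorted(scores, key=lambda s: (s.sv_id, s.gene_id, s.tissue)):
        cur = best.get(s.sv_id)
        if cur is None or s.score > cur.score:
            best[s.sv_id] = s
    selected = [best[k] for k in sorted(best)]
    vals = np.array([s.score for s in selected])
    if len(selected) < 12:
        warnings.warn(
            f"only {len(selected)} SVs; using coarse 2-bin split", stacklevel=2
        )
        med = np.quantile(vals, 0.5) if len(selected) else 0.0
        for s in selected:
            s.bin = 1 if s.score <= med else 2
        return selected
    qs = np.quantile(vals, [0.5, 0.6, 0.7, 0.8, 0.9])
    for s in selected:
        s.bin = 1 + int(np.sum(s.score > qs))
    return selected
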