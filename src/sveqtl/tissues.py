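"""Cross-tissue eQTL activity via per-tissue posterior probabilities
(m-values) and constitutive / tissue-specific classification.

The model: each tissue is independently active with prior probability
``prior_active``; active tissues share one fixed effect mu with prior
N(0, prior_effect_sd^2); a tissue's observed effect estimate beta_t is
N(mu, se_t^2) when active and N(0, se_t^2) when inactive.  The m-value of
tissue t is the posterior probability that t is active, summed over all
2^T activity configurations (exact enumeration for T <= 14) or approximated
by Metropolis MCMC with single-tissue flip proposals for larger T.

Activity status: active (m > 0.9), inactive (m < 0.1), ambiguous otherwise.
An eQTL is usable for tissue-specificity summaries when its status is known
in at least ``known_min`` tissues, and constitutively active when active in
at least 75% of tissues with known status.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MValueProfile",
    "McmcResult",
    "mvalues_exact",
    "mvalues_mcmc",
    "build_profile",
    "classify_specificity",
]

EXACT_MAX_TISSUES = 14
ACTIVE_THRESHOLD = 0.9
INACTIVE_THRESHOLD = 0.1

_LOG_2PI = np.log(2.0 * np.pi)


def _check_inputs(betas, ses):
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.shape != s.shape or b.ndim != 1:
        raise ValueError("betas and ses must be 1-D and the same length")
    if np.any(s <= 0) or np.any(~np.isfinite(s)) or np.any(~np.isfinite(b)):
        raise ValueError("standard errors must be positive and finite")
    return b, s


def _config_logliks(masks: np.ndarray, b: np.ndarray, s: np.ndarray, sd: float) -> np.ndarray:
    """Log-likelihood of the data under each activity configuration (rows of
    the boolean ``masks`` matrix), integrating the shared active effect over
    its N(0, sd^2) prior in closed form."""
    inact = -0.5 * _LOG_2PI - np.log(s) - 0.5 * (b / s) ** 2
    w1 = b / s**2
    w2 = (b / s) ** 2
    m = masks.astype(float)
    k = m.sum(axis=1)
    s1 = m @ w1
    s2 = m @ w2
    slog = m @ np.log(s)
    P = 1.0 / sd**2 + m @ (1.0 / s**2)
    ll_active = (
        -0.5 * k * _LOG_2PI - slog - np.log(sd) - 0.5 * np.log(P)
        - 0.5 * s2 + 0.5 * s1**2 / P
    )
    ll_active = np.where(k > 0, ll_active, 0.0)
    ll_inactive = (1.0 - m) @ inact
    return ll_active + ll_inactive


def mvalues_exact(
    betas: np.ndarray,
    ses: np.ndarray,
    prior_active: float = 0.5,
    prior_effect_sd: float = 0.3,
) -> np.ndarray:
    """Exact m-values by enumeration over all 2^T activity configurations
    (T <= 14)."""
    b, s = _check_inputs(betas, ses)
    T = b.size
    if T > EXACT_MAX_TISSUES:
        raise ValueError(f"exact enumeration limited to T <= {EXACT_MAX_TISSUES}")
    n_cfg = 1 << T
    masks = ((np.arange(n_cfg)[:, None] >> np.arange(T)) & 1).astype(bool)
    ll = _config_logliks(masks, b, s, prior_effect_sd)
    k = masks.sum(axis=1)
    logprior = k * np.log(prior_active) + (T - k) * np.log1p(-prior_active)
    logw = ll + logprior
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    return w @ masks


@dataclass
class McmcResult:
    m: np.ndarray
    n_kept: int
    split_disagreement: float
    converged: bool


def mvalues_mcmc(
    betas: np.ndarray,
    ses: np.ndarray,
    prior_active: float = 0.5,
    prior_effect_sd: float = 0.3,
    n_iter: int = 100_000,
    burn_in: int = 10_000,
    seed: int = 0,
) -> McmcResult:
    """Metropolis approximation of the m-values over activity configurations,
    deterministic under seed.

    Proposals mix single-tissue flips (90%), double flips (5%) and
    independence draws from a per-tissue marginal-evidence product
    distribution (5%, Metropolis–Hastings corrected) — the shared-effect
    likelihood makes the posterior sharply multimodal and the independence
    moves let the chain jump between modes.  Burn-in anneals the target from
    flat to the full posterior and the chain starts from the marginal
    evidence (|beta/se| > 2).  Flags non-convergence when the two
    post-burn-in half-chains disagree on any m-value by more than 0.05."""
    b, s = _check_inputs(betas, ses)
    T = b.size
    if T < 2:
        raise ValueError("MCMC needs at least 2 tissues")
    if n_iter < 10_000:
        raise ValueError("n_iter must be at least 10,000")
    rng = np.random.default_rng(seed)
    log_pa = np.log(prior_active)
    log_pi = np.log1p(-prior_active)

    cache: dict[int, float] = {}

    def logpost(key: int, mask: np.ndarray) -> float:
        val = cache.get(key)
        if val is None:
            k = int(mask.sum())
            ll = float(_config_logliks(mask[None, :], b, s, prior_effect_sd)[0])
            val = ll + k * log_pa + (T - k) * log_pi
            cache[key] = val
        return val

    def mask_key(m):
        return int.from_bytes(np.packbits(m, bitorder="little").tobytes(), "little")

    # Independence proposal: mixture of two per-tissue product distributions,
    # one favouring the positive-effect tissues and one the negative-effect
    # tissues (active tissues share one effect, so high-posterior
    # configurations are sign-coherent).
    var1 = prior_effect_sd**2 + s**2
    log_bf1 = -0.5 * np.log(var1 / s**2) - 0.5 * b**2 * (1 / var1 - 1 / s**2)
    odds = np.exp(np.clip(log_bf1, -30, 30)) * prior_active / (1 - prior_active)
    q = np.clip(odds / (1 + odds), 0.05, 0.95)
    q_pos = np.where(b > 0, q, 0.05)
    q_neg = np.where(b < 0, q, 0.05)

    def logprop(m):
        comp = [
            float(m @ np.log(qq) + (~m) @ np.log1p(-qq)) for qq in (q_pos, q_neg)
        ]
        hi = max(comp)
        return hi + np.log(0.5 * sum(np.exp(c - hi) for c in comp))

    mask = np.abs(b / s) > 2.0
    cur = logpost(mask_key(mask), mask)
    counts = np.zeros(T, dtype=np.int64)
    half = np.zeros((2, T), dtype=np.int64)
    n_kept = n_iter - burn_in
    flips = rng.integers(0, T, size=(n_iter, 2))
    move = rng.random(n_iter)  # <0.05 double flip, <0.10 independence draw
    ind_draws = rng.random((n_iter, T))
    us = np.log(rng.random(n_iter))
    for it in range(n_iter):
        temp = min(1.0, it / max(burn_in, 1))  # annealed burn-in
        if move[it] < 0.05:
            prev = mask.copy()
            j, j2 = flips[it]
            mask[j] = ~mask[j]
            if j2 != j:
                mask[j2] = ~mask[j2]
            correction = 0.0
        elif move[it] < 0.15:
            prev = mask.copy()
            qq = q_pos if move[it] < 0.10 else q_neg
            mask = ind_draws[it] < qq
            correction = logprop(prev) - logprop(mask)
        else:
            prev = mask.copy()
            j = flips[it, 0]
            mask[j] = ~mask[j]
            correction = 0.0
        prop = logpost(mask_key(mask), mask)
        if temp * (prop - cur) + correction >= us[it]:
            cur = prop
        else:
            mask = prev
        if it >= burn_in:
            counts += mask
            half[0 if it - burn_in < n_kept // 2 else 1] += mask
    m = counts / n_kept
    h0 = half[0] / max(n_kept // 2, 1)
    h1 = half[1] / max(n_kept - n_kept // 2, 1)
    disagreement = float(np.max(np.abs(h0 - h1))) if n_kept else np.inf
    converged = disagreement <= 0.05
    if not converged:
        warnings.warn(
            f"MCMC split-chain disagreement {disagreement:.3f} > 0.05", stacklevel=2
        )
    return McmcResult(m=m, n_kept=n_kept, split_disagreement=disagreement, converged=converged)


@dataclass
class MValueProfile:
    """Per-tissue activity profile of one eQTL (variant/gene pair)."""

    variant_id: str
    gene_id: str
    tissues: list[str]
    betas: np.ndarray
    ses: np.ndarray
    m: np.ndarray
    group: str = ""
    converged: bool = True

    @property
    def statuses(self) -> np.ndarray:
        """'active' (m > 0.9), 'inactive' (m < 0.1), 'ambiguous', or
        'missing' where the input effect was unavailable (NaN)."""
        out = np.full(len(self.tissues), "ambiguous", dtype=object)
        out[self.m > ACTIVE_THRESHOLD] = "active"
        out[self.m < INACTIVE_THRESHOLD] = "inactive"
        out[~np.isfinite(self.betas)] = "missing"
        return out

    @property
    def n_known(self) -> int:
        st = self.statuses
        return int(np.sum((st == "active") | (st == "inactive")))

    @property
    def n_active(self) -> int:
        return int(np.sum(self.statuses == "active"))

    def activity_proportion(self) -> float:
        """Fraction of known-status tissues in which the eQTL is active."""
        k = self.n_known
        return self.n_active / k if k else np.nan

    def is_constitutive(self, threshold: float = 0.75) -> bool:
        k = self.n_known
        return k > 0 and self.n_active / k >= threshold


def build_profile(
    variant_id: str,
    gene_id: str,
    tissues: list[str],
    betas: np.ndarray,
    ses: np.ndarray,
    group: str = "",
    prior_active: float = 0.5,
    prior_effect_sd: float = 0.3,
    mcmc_kwargs: dict | None = None,
) -> MValueProfile:
    """m-value profile for one eQTL; exact enumeration for T <= 14 tissues
    with available effects, MCMC beyond.  Missing tissues (NaN beta or se)
    get status 'missing' and do not enter the meta-analysis."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    avail = np.isfinite(b) & np.isfinite(s) & (s > 0)
    m = np.full(b.size, np.nan)
    converged = True
    if avail.sum() > 0:
        if avail.sum() <= EXACT_MAX_TISSUES:
            m[avail] = mvalues_exact(b[avail], s[avail], prior_active, prior_effect_sd)
        else:
            res = mvalues_mcmc(
                b[avail], s[avail], prior_active, prior_effect_sd, **(mcmc_kwargs or {})
            )
            m[avail] = res.m
            converged = res.converged
    return MValueProfile(
        variant_id=variant_id, gene_id=gene_id, tissues=list(tissues),
        betas=b, ses=s, m=m, group=group, converged=converged,
    )


def classify_specificity(
    profiles: list[MValueProfile],
    known_min: int = 43,
    constitutive_threshold: float = 0.75,
) -> pd.DataFrame:
    """Per-group constitutive fractions and activity-proportion summaries.

    Profiles with fewer than ``known_min`` known-status tissues are dropped.
    Reported per group: number of usable eQTLs, fraction constitutively
    active, fraction active in 100% of known tissues, and the mean activity
    proportion.  Empty groups are omitted.
    """
    rows: dict[str, list[MValueProfile]] = {}
    for p in profiles:
        if p.n_known >= known_min:
            rows.setdefault(p.group, []).append(p)
    out = []
    for group in sorted(rows):
        ps = rows[group]
        props = np.array([p.activity_proportion() for p in ps])
        out.append(
            {
                "group": group,
                "n": len(ps),
                "fraction_constitutive": float(
                    np.mean([p.is_constitutive(constitutive_threshold) for p in ps])
                ),
                "fraction_active_all_known": float(np.mean(props == 1.0)),
                "mean_activity_proportion": float(props.mean()),
            }
        )
    return pd.DataFrame(out).set_index("group") if out else pd.DataFrame(
        columns=["n", "fraction_constitutive", "fraction_active_all_known",
                 "mean_activity_proportion"]
    )
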