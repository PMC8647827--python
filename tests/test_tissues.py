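import math

import numpy as np
import pytest

from sveqtl.tissues import (
    MValueProfile,
    build_profile,
    classify_specificity,
    mvalues_exact,
    mvalues_mcmc,
)


def _oracle_two_tissue(b, s, pa=0.5, sd=0.3):
    """Independent four-configuration enumeration with plain-float math."""

    def norm_pdf(x, var):
        return math.exp(-0.5 * x * x / var) / math.sqrt(2 * math.pi * var)

    def marginal_active(idx):
        # integrate prod_i N(b_i; mu, s_i^2) * N(mu; 0, sd^2) dmu
        prec = 1 / sd**2 + sum(1 / s[i] ** 2 for i in idx)
        mean_num = sum(b[i] / s[i] ** 2 for i in idx)
        log = (
            -0.5 * len(idx) * math.log(2 * math.pi)
            - sum(math.log(s[i]) for i in idx)
            - math.log(sd)
            - 0.5 * math.log(prec)
            - 0.5 * sum(b[i] ** 2 / s[i] ** 2 for i in idx)
            + 0.5 * mean_num**2 / prec
        )
        return math.exp(log)

    weights = {}
    for cfg in [(0, 0), (0, 1), (1, 0), (1, 1)]:
        active = [i for i in range(2) if cfg[i]]
        lik = marginal_active(active) if active else 1.0
        for i in range(2):
            if not cfg[i]:
                lik *= norm_pdf(b[i], s[i] ** 2)
        weights[cfg] = lik * pa ** sum(cfg) * (1 - pa) ** (2 - sum(cfg))
    tot = sum(weights.values())
    return [
        sum(w for cfg, w in weights.items() if cfg[i]) / tot for i in range(2)
    ]


class TestExact:
    def test_single_null_tissue_inactive(self):
        (m,) = mvalues_exact([0.0], [0.01])
        assert m < 0.1

    def test_two_strong_concordant_tissues_active(self):
        m = mvalues_exact([1.0, 1.0], [0.1, 0.1])
        assert (m > 0.9).all()

    def test_matches_four_configuration_oracle(self, rng):
        for _ in range(25):
            b = rng.normal(0, 0.5, 2)
            s = rng.uniform(0.05, 0.4, 2)
            got = mvalues_exact(b, s)
            want = _oracle_two_tissue(list(b), list(s))
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_exchangeable_tissues_identical_m(self):
        m = mvalues_exact([0.4, 0.4, 0.4], [0.2, 0.2, 0.2])
        assert np.ptp(m) < 1e-12

    def test_permutation_equivariance(self, rng):
        b = rng.normal(0, 0.5, 6)
        s = rng.uniform(0.05, 0.3, 6)
        m = mvalues_exact(b, s)
        perm = rng.permutation(6)
        np.testing.assert_allclose(mvalues_exact(b[perm], s[perm]), m[perm], atol=1e-12)

    def test_monotone_in_effect_strength(self):
        base = np.array([0.1, 0.3, -0.2, 0.0])
        ses = np.full(4, 0.15)
        prev = -1.0
        for scale in (0.0, 0.5, 1.0, 2.0, 4.0):
            b = base.copy()
            b[1] = 0.3 * max(scale, 0.05)
            m = mvalues_exact(b, ses)[1]
            assert m >= prev - 1e-9
            prev = m

    def test_input_validation(self):
        with pytest.raises(ValueError):
            mvalues_exact([0.1], [0.0])
        with pytest.raises(ValueError):
            mvalues_exact(np.zeros(15), np.ones(15))


class TestMcmc:
    def test_agrees_with_exact_for_ten_tissues(self):
        rng = np.random.default_rng(2)  # a sign-mixed, multimodal dataset
        b = rng.normal(0, 0.5, 10)
        s = rng.uniform(0.05, 0.3, 10)
        exact = mvalues_exact(b, s)
        res = mvalues_mcmc(b, s, n_iter=100_000, burn_in=10_000, seed=17)
        assert np.abs(res.m - exact).max() <= 0.03

    def test_null_tissues_inactive_when_effect_pinned_elsewhere(self):
        """Tissues with beta ~ 0 are called inactive (m < 0.1) once other
        tissues establish a strong shared effect; a fully-null profile is
        genuinely ambiguous under the shared-effect model (the all-active
        configuration with mu ~ 0 pays its Occam penalty only once), so
        inactivity is only decidable against a nonzero effect."""
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(500 + seed)
            b = np.concatenate([np.full(3, 1.0), rng.normal(0, 0.05, 3)])
            s = np.full(6, 0.05)
            res = mvalues_mcmc(b, s, n_iter=20_000, burn_in=5_000, seed=seed)
            ok += (res.m[:3] > 0.9).all() and (res.m[3:] < 0.1).all()
        assert ok >= 9

    def test_deterministic_under_seed(self, rng):
        b = rng.normal(0, 0.5, 5)
        s = rng.uniform(0.1, 0.3, 5)
        r1 = mvalues_mcmc(b, s, n_iter=20_000, burn_in=5_000, seed=9)
        r2 = mvalues_mcmc(b, s, n_iter=20_000, burn_in=5_000, seed=9)
        np.testing.assert_array_equal(r1.m, r2.m)

    def test_rejects_bad_sizes(self):
        with pytest.raises(ValueError):
            mvalues_mcmc([0.1], [0.1])
        with pytest.raises(ValueError):
            mvalues_mcmc([0.1, 0.2], [0.1, 0.1], n_iter=500)


class TestProfiles:
    def _profile(self, m, betas=None, tissues=None):
        m = np.asarray(m, dtype=float)
        T = m.size
        betas = np.ones(T) if betas is None else np.asarray(betas, float)
        return MValueProfile(
            "v", "g", tissues or [f"t{i}" for i in range(T)],
            betas, np.full(T, 0.1), m,
        )

    def test_status_thresholds(self):
        p = self._profile([0.95, 0.05, 0.5])
        assert list(p.statuses) == ["active", "inactive", "ambiguous"]
        assert p.n_known == 2

    def test_constitutive_fraction_rule(self):
        # active in 40 of 45 known: 0.889 >= 0.75 -> constitutive
        m = np.concatenate([np.full(40, 0.95), np.full(5, 0.05), np.full(3, 0.5)])
        p = self._profile(m)
        assert p.n_known == 45
        assert p.is_constitutive()

    def test_insufficiently_known_profiles_dropped(self):
        # 42 known of 48 with known_min 43 -> excluded from summaries
        m = np.concatenate([np.full(42, 0.95), np.full(6, 0.5)])
        good = np.full(48, 0.95)
        df = classify_specificity(
            [self._profile(m), self._profile(good)], known_min=43
        )
        assert df.loc["", "n"] == 1

    def test_missing_effects_marked(self):
        p = build_profile("v", "g", ["a", "b", "c"],
                          np.array([0.5, np.nan, 0.5]), np.array([0.1, 0.1, 0.1]))
        assert p.statuses[1] == "missing"
        assert np.isnan(p.m[1])


def test_constitutive_coding_sv_vs_tissue_restricted_snv():
    """Planted constitutive coding-SV effects classify as more constitutive
    than planted tissue-restricted SNV effects."""
    from sveqtl import CohortConfig, EqtlEffect, generate_cohort
    from sveqtl.pipeline import cross_tissue_profiles, run_eqtl

    effects = []
    for i in range(6):  # coding SVs, all tissues
        effects.append(EqtlEffect(f"DEL_{i:05d}", (f"gene_{i:05d}",), 3.0, None, True))
    for i in range(6):  # SNVs restricted to one tissue
        effects.append(
            EqtlEffect(f"SNV_{i:05d}", (f"gene_{i + 20:05d}",), 3.0, ("tissue_1",), False)
        )
    cfg = CohortConfig(
        n_samples=120, n_genes=60, n_tissues=4, seed=77,
        class_counts={"DEL": 30, "DUP": 10, "mCNV": 5, "INV": 5, "BND": 5,
                      "MEI": 5, "SNV": 400, "INDEL": 40},
        eqtl_effects=effects,
    )
    c = generate_cohort(cfg)
    res, vm, rp = run_eqtl(c, n_perm=150, seed=3)
    profiles = cross_tissue_profiles(c, res, rp)
    df = classify_specificity(profiles, known_min=3)
    assert "coding_SV" in df.index
    sv_frac = df.loc["coding_SV", "fraction_constitutive"]
    snv_frac = (
        df.loc["noncoding_SNV_indel", "fraction_constitutive"]
        if "noncoding_SNV_indel" in df.index else 0.0
    )
    assert sv_frac > snv_frac
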