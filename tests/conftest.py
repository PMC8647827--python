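import numpy as np
import pytest

from sveqtl import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with planted common-eQTL and rare-outlier effects,
    shared across read-only tests."""
    cfg = CohortConfig(
        n_samples=80,
        n_genes=80,
        n_tissues=3,
        class_counts={
            "DEL": 40, "DUP": 20, "mCNV": 10, "INV": 8, "BND": 8, "MEI": 10,
            "SNV": 500, "INDEL": 60,
        },
        n_eqtl_effects=8,
        eqtl_sv_fraction=0.5,
        n_rare_svs=20,
        n_rare_outlier_effects=8,
        outlier_magnitude=7.0,
        seed=1234,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """No planted effects at all: expression is covariates + noise."""
    cfg = CohortConfig(
        n_samples=80,
        n_genes=60,
        n_tissues=2,
        class_counts={"DEL": 30, "DUP": 10, "SNV": 400, "INDEL": 40,
                      "mCNV": 5, "INV": 5, "BND": 5, "MEI": 5},
        seed=99,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
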