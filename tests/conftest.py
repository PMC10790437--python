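import numpy as np
import pytest

from sncsig import preprocess, simcohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-config cohort shared across tests (seed 1)."""
    cfg = simcohort.SimConfig(seed=1)
    counts, pheno, truth = simcohort.generate_cohort(cfg)
    return cfg, counts, pheno, truth


@pytest.fixture(scope="session")
def clean_cohort():
    """Artifact-free cohort (no missing cells / outliers), seed 2."""
    cfg = simcohort.SimConfig(seed=2)
    counts, pheno, truth = simcohort.generate_cohort(cfg, inject=False)
    return cfg, counts, pheno, truth


@pytest.fixture(scope="session")
def preprocessed(clean_cohort):
    cfg, counts, pheno, truth = clean_cohort
    em, filtered = preprocess.preprocess_pipeline(
        counts, impute_method="feature_median"
    )
    return em, filtered, pheno, truth


def toy_count_matrix(counts, missing=None):
    counts = np.asarray(counts)
    nf, ns = counts.shape
    return simcohort.CountMatrix(
        counts=counts,
        feature_ids=np.array([f"f{i}" for i in range(nf)], dtype=object),
        feature_class=np.array(["miRNA"] * nf, dtype=object),
        sample_ids=np.array([f"s{j}" for j in range(ns)], dtype=object),
        missing=missing,
    )
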