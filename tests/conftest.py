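import numpy as np
import pandas as pd
import pytest

from threebias import CountMatrix, GeneAnnotation, SimConfig, simulate_counts

TWO_GROUP_DESIGN = (("male", 2, "torin"), ("male", 2, "control"))


def make_count_matrix(counts: np.ndarray, gene_ids=None, sample_ids=None,
                      diets=None) -> CountMatrix:
    """Hand-built CountMatrix with a minimal valid sample sheet."""
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_samples)]
    diets = diets or ["torin"] * (n_samples // 2) + ["control"] * (n_samples - n_samples // 2)
    meta = pd.DataFrame(
        {
            "sex": "male",
            "age_weeks": 2,
            "diet": diets,
            "replicate": range(1, n_samples + 1),
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    return CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids), meta)


@pytest.fixture(scope="session")
def null_experiment():
    """Small unbiased null experiment (equal tau, no effects)."""
    cfg = SimConfig(n_genes=400, design=TWO_GROUP_DESIGN, dispersion=0.1,
                    lib_size=2e5, seed=7)
    return simulate_counts(cfg)


@pytest.fixture(scope="session")
def biased_null_experiment():
    """Null experiment with a 4-fold tau imbalance between diets."""
    cfg = SimConfig(
        n_genes=800,
        design=TWO_GROUP_DESIGN,
        dispersion=0.1,
        bias_tau={"torin": 1000.0, "control": 4000.0},
        lib_size=5e5,
        seed=7,
    )
    return simulate_counts(cfg)


@pytest.fixture()
def simple_annotation():
    return GeneAnnotation(pd.Series([10.0, 100.0, 1000.0], index=["g0", "g1", "g2"]))
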