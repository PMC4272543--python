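import warnings

import numpy as np
import pandas as pd
import pytest

from pomebrown import (
    CountMatrix,
    GeneAnnotation,
    SampleTable,
    SimConfig,
    classify_samples,
    compute_rpkm,
    generate_experiment,
)

# NIPALS legitimately warns when factor extraction exhausts the rank on
# tiny instances; keep test output readable.
warnings.filterwarnings("ignore", message="NIPALS deflation degenerate")
warnings.filterwarnings("ignore", message=".*exceeds rank.*")


@pytest.fixture
def tiny_counts():
    return CountMatrix(
        pd.DataFrame(
            {"s1": [10, 0, 5], "s2": [3, 7, 1]},
            index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
        )
    )


@pytest.fixture
def tiny_annotation():
    return GeneAnnotation(
        pd.DataFrame(
            {"cds_length_bp": [1000, 500, 2000], "bin_label": ["stress", "", "energy"]},
            index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
        )
    )


@pytest.fixture
def tiny_samples():
    return SampleTable(
        pd.DataFrame(
            {
                "tissue": ["inner", "inner"],
                "timepoint": ["stored", "stored"],
                "browning_index": [2.0, 8.0],
                "total_mapped_reads": [1_000_000, 2_000_000],
            },
            index=pd.Index(["s1", "s2"], name="sample_id"),
        )
    )


@pytest.fixture(scope="session")
def small_experiment():
    """A small planted experiment shared by slower tests."""
    cfg = SimConfig(n_genes=400, n_browning_genes=12, n_ripening_genes=12, seed=11)
    counts, genes, samples, truth = generate_experiment(cfg)
    expr = compute_rpkm(counts, genes, samples)
    samples = classify_samples(samples)
    return counts, genes, samples, expr, truth


def two_class_frame(rng, n=16, p=50):
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"g{i}" for i in range(p)])
    y = pd.Series(np.repeat([0.0, 1.0], [n // 2, n - n // 2]))
    return X, y
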