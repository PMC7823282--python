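import numpy as np
import pandas as pd
import pytest

from refnof1 import CountMatrix


@pytest.fixture
def toy_counts() -> CountMatrix:
    """4 genes x 4 samples (2 per condition); overall means 10, 0.5, 55, 5."""
    counts = pd.DataFrame(
        {
            "s1": [10, 1, 60, 5],
            "s2": [12, 1, 50, 5],
            "s3": [8, 0, 55, 5],
            "s4": [10, 0, 55, 5],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    design = pd.Series({"s1": "A", "s2": "A", "s3": "B", "s4": "B"})
    return CountMatrix(counts, design)


@pytest.fixture
def toy_tsv(tmp_path, toy_counts):
    """The toy matrix written as count + design TSVs."""
    counts_path = tmp_path / "counts.tsv"
    design_path = tmp_path / "design.tsv"
    toy_counts.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    pd.DataFrame({"sample_id": toy_counts.design.index,
                  "condition": toy_counts.design.values}
                 ).to_csv(design_path, sep="\t", index=False)
    return counts_path, design_path


def random_count_matrix(rng: np.random.Generator, n_genes: int = 30,
                        n_per_condition: int = 4,
                        mean: float = 50.0) -> CountMatrix:
    """Small Poisson matrix for property tests."""
    counts = rng.poisson(mean, size=(n_genes, 2 * n_per_condition))
    samples = [f"a{i}" for i in range(n_per_condition)] + \
              [f"b{i}" for i in range(n_per_condition)]
    design = pd.Series(["A"] * n_per_condition + ["B"] * n_per_condition,
                       index=samples)
    return CountMatrix(
        pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)],
                     columns=samples),
        design,
    )
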