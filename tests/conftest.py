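import numpy as np
import pandas as pd
import pytest

from stromasig import make_expression_matrix


@pytest.fixture
def small_matrix():
    """2 genes x 3 samples, fully observed."""
    return make_expression_matrix(
        np.array([[0.5, -1.25, 2.0], [1.0, 0.0, -0.5]]),
        probe_ids=["P1", "P2"],
        sample_ids=["s1", "s2", "s3"],
        gene_symbols=["GENEA", "GENEB"],
        unigene_ids=["Hs.1", "Hs.2"],
    )


@pytest.fixture
def paired_matrix():
    """4 genes x 4 samples in 2 stimulated/unstimulated pairs."""
    rng = np.random.default_rng(7)
    return make_expression_matrix(
        rng.normal(size=(4, 4)),
        probe_ids=[f"P{i}" for i in range(4)],
        sample_ids=["u1", "u2", "s1", "s2"],
        gene_symbols=[f"G{i}" for i in range(4)],
        treatments=["unstimulated", "unstimulated", "stimulated", "stimulated"],
        pair_ids=["a", "b", "a", "b"],
        cell_types=["f"] * 4,
    )


def random_expression_matrix(rng, n_genes=5, n_samples=4, missing_rate=0.15):
    """Random valid matrix for roundtrip property tests."""
    values = np.round(rng.normal(size=(n_genes, n_samples)), 6)
    mask = rng.random(values.shape) < missing_rate
    values[mask] = np.nan
    return make_expression_matrix(
        values,
        probe_ids=[f"P{i}" for i in range(n_genes)],
        sample_ids=[f"s{j}" for j in range(n_samples)],
        gene_symbols=[f"G{i}" for i in range(n_genes)],
        unigene_ids=[f"HS.{i}" if i % 2 else "" for i in range(n_genes)],
        treatments=["stimulated" if j % 2 else "unstimulated" for j in range(n_samples)],
        pair_ids=[f"p{j // 2}" for j in range(n_samples)],
        cell_types=["f"] * n_samples,
    )
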