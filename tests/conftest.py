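import numpy as np
import pandas as pd
import pytest

from cernet.containers import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_count_matrix(arr, n_a, n_b, gene_ids=None):
    """Helper: CountMatrix from an array with the first n_a columns group A."""
    arr = np.asarray(arr)
    samples = [f"S{i+1}" for i in range(n_a + n_b)]
    genes = gene_ids or [f"G{i+1}" for i in range(arr.shape[0])]
    counts = pd.DataFrame(arr, index=genes, columns=samples)
    groups = pd.Series(["A"] * n_a + ["B"] * n_b, index=samples)
    return CountMatrix(counts, groups)


@pytest.fixture
def small_nb_dataset():
    """A modest synthetic dataset with triplets, shared across tests."""
    from cernet.simulate import SyntheticConfig, generate_dataset

    cfg = SyntheticConfig(n_per_group=10, n_lnc=25, n_mi=12, n_mrna=40,
                          frac_de=0.2, n_triplets=6, coupling=0.9, seed=99)
    return generate_dataset(cfg)
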