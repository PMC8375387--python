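import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from gsdiscrim import ExpressionDataset

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


def make_dataset(
    n_genes: int = 50,
    n1: int = 5,
    n2: int = 5,
    seed: int = 0,
    delta: float = 0.0,
    affected=(),
    gene_sd: float = 1.0,
) -> ExpressionDataset:
    """Small two-group Gaussian dataset with an optional shift in ``affected`` genes."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(n_genes)]
    samples = [f"c{i}" for i in range(n1)] + [f"t{i}" for i in range(n2)]
    values = pd.DataFrame(
        rng.normal(8.0, gene_sd, size=(n_genes, n1 + n2)), index=genes, columns=samples
    )
    for g in affected:
        values.loc[g, samples[n1:]] += delta
    groups = pd.Series(["ctrl"] * n1 + ["cond"] * n2, index=samples)
    return ExpressionDataset(values, groups=groups, condition="cond")


@pytest.fixture
def dataset():
    return make_dataset()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
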