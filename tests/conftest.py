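import numpy as np
import pandas as pd
import pytest

from shambhala import ExpressionMatrix


def make_matrix(values, genes=None, samples=None, role="R") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), role=role)


@pytest.fixture
def random_matrix():
    def _make(n_genes=50, n_samples=8, seed=0, loc=8.0, scale=2.0, role="R"):
        rng = np.random.default_rng(seed)
        return make_matrix(rng.normal(loc, scale, size=(n_genes, n_samples)), role=role)

    return _make
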