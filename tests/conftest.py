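import numpy as np
import pandas as pd
import pytest

from coexrewire.datamodel import AnalysisConfig, ExpressionDataset


def make_dataset(matrix: np.ndarray, n1: int, n2: int,
                 genes=None, name="test") -> ExpressionDataset:
    """Wrap a raw array as a two-condition dataset (first n1 columns = cond1)."""
    n_genes, n_samples = matrix.shape
    assert n_samples == n1 + n2
    genes = genes or [f"G{i:03d}" for i in range(n_genes)]
    samples = [f"s{i:03d}" for i in range(n_samples)]
    design = {s: ("early" if i < n1 else "late")
              for i, s in enumerate(samples)}
    return ExpressionDataset(
        matrix=pd.DataFrame(matrix, index=genes, columns=samples),
        design=design, conditions=("early", "late"), name=name)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_cfg():
    return AnalysisConfig(n_perm_gsnca=50, n_perm_hub=10, rng_seed=7)


@pytest.fixture
def small_dataset(rng):
    """10 genes x (6+6) samples of pure noise."""
    return make_dataset(rng.standard_normal((10, 12)), 6, 6)
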