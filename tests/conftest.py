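import numpy as np
import pandas as pd
import pytest

from sttransfer.io import ExpressionDataset
from sttransfer.simulate import (PseudoLayout, SyntheticReferenceSpec,
                                 make_pseudo_st, make_synthetic_reference)


@pytest.fixture(scope="session")
def small_spec() -> SyntheticReferenceSpec:
    """Down-scaled reference spec for fast unit tests."""
    return SyntheticReferenceSpec(n_types=3, cells_per_type=120, n_genes=120,
                                  signature_genes_per_type=10, seed=7)


@pytest.fixture(scope="session")
def small_reference(small_spec) -> ExpressionDataset:
    return make_synthetic_reference(small_spec)


@pytest.fixture(scope="session")
def small_pair(small_reference):
    """A small gene-aligned (reference, spatial) pair with ground truth."""
    st = make_pseudo_st(
        small_reference,
        PseudoLayout(kind="hierarchical", n_nonbg_types=3, cells_per_nonbg_type=120),
        seed=8)
    return small_reference, st


def make_tiny_dataset(role="reference", n=3, d=4, seed=0, labels=None):
    rng = np.random.default_rng(seed)
    return ExpressionDataset(
        counts=rng.poisson(3.0, size=(n, d)).astype(np.int64),
        gene_ids=[f"g{j}" for j in range(d)],
        cell_ids=[f"c{i}" for i in range(n)],
        coords=rng.uniform(0, 10, size=(n, 2)) if role == "spatial" else None,
        labels=pd.Categorical(labels) if labels is not None else None,
        batch=role,
    )
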