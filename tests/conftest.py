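import numpy as np
import pandas as pd
import pytest

from refstab.qpcr_data import CtMatrix, SampleMeta


def make_ct(values, genes=None, groups=None, donors=None, gene_role=None):
    """Build a CtMatrix from a 2-D array with minimal boilerplate."""
    arr = np.asarray(values, dtype=float)
    n, k = arr.shape
    genes = genes or [f"G{j + 1}" for j in range(k)]
    groups = groups or ["grp"] * n
    donors = donors or [f"d{i + 1}" for i in range(n)]
    samples = [
        SampleMeta(f"s{i + 1}", donors[i], groups[i]) for i in range(n)
    ]
    return CtMatrix(pd.DataFrame(arr, columns=genes), samples, gene_role=gene_role)


@pytest.fixture
def small_matrix():
    """3 genes × 4 samples with hand-written Cts (used against brute force)."""
    return make_ct(
        [[10.0, 12.1, 15.3],
         [10.4, 12.0, 15.9],
         [10.1, 12.6, 15.2],
         [10.7, 12.2, 15.8]],
        genes=["A", "B", "C"],
    )


@pytest.fixture
def twelve_sample_matrix():
    """12 samples in 3 groups × 4 donors, 5 HKGs + 2 targets, deterministic."""
    rng = np.random.default_rng(42)
    ct = rng.normal(15.0, 1.0, size=(12, 7))
    groups = ["BMSC"] * 4 + ["ASC"] * 4 + ["hAMSC"] * 4
    donors = [f"d{i % 4 + 1}" for i in range(12)]
    genes = ["ACTB", "EF1A", "GAPDH", "RPLP0", "TBP", "ICAM1", "IL8"]
    return make_ct(
        ct, genes=genes, groups=groups, donors=donors,
        gene_role={"ICAM1": "target", "IL8": "target"},
    )
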