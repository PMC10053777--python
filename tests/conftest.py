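import numpy as np
import pandas as pd
import pytest

from mixturetox import synthdata as sd
from mixturetox.diffexpr import CountMatrix


@pytest.fixture(scope="session")
def small_null_counts():
    """5,000 null NB genes, three groups of three replicates, alpha=0.05."""
    truth = sd.SynthTruth(theta=np.zeros(5000), alpha=0.05, seed=101)
    cm, truth = sd.gen_counts(5000, 3, truth)
    return cm, truth


@pytest.fixture(scope="session")
def planted_dataset():
    """Mixture-design dataset with 10% planted DE genes and gene sets."""
    truth = sd.make_truth(4000, de_fraction=0.1, beta=0.59, eps_sd=0.3, alpha=0.05, seed=7)
    cm, truth = sd.gen_counts(4000, 3, truth)
    coll = sd.gen_genesets(80, (15, 400), truth=truth, n_active=8)
    return cm, truth, coll


@pytest.fixture
def toy_counts():
    """Tiny hand-written count matrix: 6 genes, 2 groups x 2 samples."""
    counts = pd.DataFrame(
        {
            "c1": [10, 0, 50, 100, 5, 0],
            "c2": [12, 0, 45, 110, 7, 0],
            "t1": [40, 0, 48, 25, 0, 3],
            "t2": [38, 0, 52, 30, 0, 2],
        },
        index=[f"g{i}" for i in range(6)],
    )
    groups = pd.Series(
        ["control", "control", "treat", "treat"], index=counts.columns, name="group"
    )
    return CountMatrix(counts, groups)
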