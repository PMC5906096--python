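import numpy as np
import pandas as pd
import pytest

from dbsomics.diffexpr import CountMatrix
from dbsomics.simulate import SimConfig


def make_samples(layout):
    """layout: list of (genotype, treatment, n); batches alternate."""
    rows = []
    for genotype, treatment, n in layout:
        for r in range(n):
            rows.append(
                {
                    "sample_id": f"{genotype}_{treatment}_{r + 1}",
                    "genotype": genotype,
                    "treatment": treatment,
                    "batch": f"b{r % 2 + 1}",
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


@pytest.fixture
def two_group_samples():
    return make_samples([("WT", "sham", 5), ("WT", "DBS", 5)])


@pytest.fixture
def small_counts(two_group_samples):
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        rng.poisson(100, size=(50, 10)),
        index=[f"g{i}" for i in range(50)],
        columns=two_group_samples.index,
    )
    return CountMatrix(counts=counts, samples=two_group_samples)


@pytest.fixture
def sim_config():
    return SimConfig(seed=7, n_genes=400)
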