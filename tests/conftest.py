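import numpy as np
import pandas as pd
import pytest

from scmetab import GeneSetCollection


def random_instance(seed, n_genes=30, n_pathways=5, n_types=4, cells_per_type=12):
    """A random expression matrix, cell-type annotation and pathway collection."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    cells = [f"c{i}" for i in range(n_types * cells_per_type)]
    expr = pd.DataFrame(
        rng.gamma(2.0, 2.0, size=(n_genes, len(cells))), index=genes, columns=cells
    )
    types = pd.Series(
        np.repeat([f"T{j}" for j in range(n_types)], cells_per_type),
        index=cells, name="cell_type",
    )
    sets = {}
    for p in range(n_pathways):
        size = int(rng.integers(3, max(4, n_genes // 2)))
        members = list(rng.choice(genes, size=size, replace=False))
        sets[f"pw{p}"] = members
    collection = GeneSetCollection(
        sets, categories={name: f"cat{i % 3}" for i, name in enumerate(sets)}
    )
    return expr, types, collection


@pytest.fixture
def small_instance():
    return random_instance(seed=0)
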