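import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from unifracx import synthdata


@pytest.fixture
def rng():
    return np.random.default_rng(20160915)


def random_instance(seed: int, max_leaves: int = 10, n_samples: int = 2):
    """A random (tree, count table) pair for oracle comparisons.

    Guarantees every sample has at least one positive count.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, max_leaves + 1))
    tree = synthdata.random_tree(n, seed, mean_length=0.5)
    counts = rng.integers(0, 12, size=(n_samples, n))
    for i in range(n_samples):
        if counts[i].sum() == 0:
            counts[i, int(rng.integers(0, n))] = 1
    table = pd.DataFrame(counts, columns=list(tree.leaf_names),
                         index=[f"s{k}" for k in range(n_samples)])
    return tree, table


@pytest.fixture
def small_instance():
    return random_instance(7)
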