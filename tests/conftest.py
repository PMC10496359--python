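import numpy as np
import pandas as pd
import pytest

from coevotest import Phylogeny, TraitTable, gen_tree


@pytest.fixture
def three_tip_tree() -> Phylogeny:
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def three_tip_table() -> TraitTable:
    return TraitTable(
        pd.DataFrame({"x": [1.0, -1.0, 0.0], "y": [2.0, 0.0, 1.0]}, index=["A", "B", "C"])
    )


@pytest.fixture
def yule16() -> Phylogeny:
    return gen_tree(16, seed=42)


@pytest.fixture
def small_panel() -> TraitTable:
    rng = np.random.default_rng(7)
    cov = np.array([[1.0, 0.6, 0.2], [0.6, 1.0, 0.2], [0.2, 0.2, 1.0]])
    x = rng.multivariate_normal(np.zeros(3), cov, size=200)
    return TraitTable(
        pd.DataFrame(x, index=[f"line_{i}" for i in range(200)], columns=["a", "b", "c"])
    )
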