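import numpy as np
import pandas as pd
import pytest

from phyloshape.phylo import CovarianceFamily, parse_newick
from phyloshape.simulate import SimulationConfig, simulate_traits, simulate_tree


@pytest.fixture
def three_taxon_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def small_tree():
    return simulate_tree(12, seed=42)


@pytest.fixture
def small_family(small_tree):
    return CovarianceFamily.from_tree(small_tree)


@pytest.fixture
def synthetic_species():
    """40-species trait table + tree + truth with the default structure."""
    config = SimulationConfig(
        n_species=40, ecotype_sizes=(8, 8, 12, 12), limb_missing_frac=0.0
    )
    tree = simulate_tree(40, seed=7)
    df, truth = simulate_traits(tree, config, seed=8)
    return tree, df, truth


@pytest.fixture
def regression_data(small_family):
    """Simple y = 1 + 0.5 x + correlated noise on the 12-taxon tree."""
    rng = np.random.default_rng(3)
    n = len(small_family.taxa)
    x = rng.standard_normal(n)
    y = 1.0 + 0.5 * x + small_family.sqrt(0.7) @ rng.standard_normal(n) * 0.2
    return pd.DataFrame({"x": x, "y": y}, index=small_family.taxa)
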