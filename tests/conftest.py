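import numpy as np
import pandas as pd
import pytest

from hydromap.phylosignal import Phylogeny
from hydromap.simulate import SimConfig, simulate_bundle

# Eight-genus fixture tree with hand-set branch lengths; the frozen reference
# numbers for it (Blomberg's K, ancestral states, rank-sum W/p) were computed
# independently in R (picante::Kcalc, phytools::fastAnc, stats::wilcox.test)
# and are asserted in the unit tests.
EIGHT_TIP_NEWICK = (
    "((((A:1.0,B:1.0):0.5,C:1.5):0.8,(D:1.2,E:1.2):1.1):0.7,"
    "((F:0.9,G:0.9):1.3,H:2.2):0.8);"
)
EIGHT_TIP_VALUES = {
    "A": -1.2, "B": -1.5, "C": -2.9, "D": -0.7,
    "E": -1.1, "F": -3.4, "G": -3.0, "H": -2.1,
}


@pytest.fixture
def eight_tip_tree():
    return Phylogeny.from_newick(EIGHT_TIP_NEWICK)


@pytest.fixture
def eight_tip_values():
    return dict(EIGHT_TIP_VALUES)


@pytest.fixture(scope="session")
def small_bundle():
    """One modest seeded synthetic study shared by read-only tests."""
    cfg = SimConfig(seed=7, n_tips=40, n_plots=40, stems_per_plot=30)
    return simulate_bundle(cfg)


@pytest.fixture
def toy_inventory():
    """Three-stem plot exercising species/genus/plot-mean gap-fill levels."""
    return pd.DataFrame(
        {
            "plot_id": ["P1"] * 3,
            "x_km": [10.0] * 3,
            "y_km": [20.0] * 3,
            "species": ["GA_sp1", "GA_sp2", "GC_sp1"],
            "genus": ["GA", "GA", "GC"],
            "family": ["F1", "F1", "FX"],
            "basal_area": [2.0, 1.0, 1.0],
            "dicot": [True, True, True],
        }
    )


@pytest.fixture
def toy_traits():
    """Trait records: GA_sp1 measured directly; GA has a second congener."""
    return pd.DataFrame(
        {
            "species": ["GA_sp1", "GA_sp3", "GB_sp1"],
            "genus": ["GA", "GA", "GB"],
            "family": ["F1", "F1", "F2"],
            "order": ["O1", "O1", "O1"],
            "site": ["S1", "S2", "S1"],
            "forest_type": ["everwet", "everwet", "long_DSL"],
            "psi50": [-2.0, -4.0, -1.0],
        }
    )


def rng_values(seed, n, loc=0.0, scale=1.0):
    return np.random.default_rng(seed).normal(loc, scale, n)
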