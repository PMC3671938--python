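import numpy as np
import pytest

from cescape.phylo import Phylogeny
from cescape.synthetic_data import SimConfig, make_landscape


@pytest.fixture(scope="session")
def tree4():
    return Phylogeny.from_newick(
        "((A:0.1,B:0.12)ab:0.05,(C:0.1,D:0.08)cd:0.06)root;")


@pytest.fixture(scope="session")
def star5():
    return Phylogeny.from_newick(
        "(A:0.12,B:0.14,C:0.12,D:0.10,E:0.20)root;")


@pytest.fixture(scope="session")
def small_sim(tree4):
    """50 kb neutral simulation with 10 planted cores, shared across tests."""
    from cescape.synthetic_data import evolve_alignment
    cfg = SimConfig(tree=tree4, length=50_000, kappa=0.0, rho=1.0, seed=3)
    ls = make_landscape(cfg, 10)
    aln, log, root = evolve_alignment(ls, cfg)
    return cfg, ls, aln, log, root


@pytest.fixture
def rng():
    return np.random.default_rng(0)
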