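import numpy as np
import pytest

import treedemog as td
from treedemog.simulate import random_tree


@pytest.fixture(scope="session")
def scheme():
    return td.ogawa_scheme()


@pytest.fixture(scope="session")
def tree17():
    return td.read_newick(random_tree(17, seed=5))


@pytest.fixture(scope="session")
def tree5():
    return td.read_newick("((A:1.2,B:0.8):0.5,((C:0.4,D:0.6):0.3,E:1.1):0.2);")


def random_valid_rates(rng, scheme, species=("sp1", "sp2")):
    """Random AnnualRates respecting every structural constraint."""
    K, C = len(species), scheme.n_classes
    psv = rng.uniform(0.2, 0.99, size=(K, C))
    pst = rng.uniform(0.3, 0.99, size=(K, C))
    pstpr = np.ones((K, C))
    for i in scheme.retro_classes:
        pstpr[:, i - 1] = rng.uniform(0.7, 0.999, size=K)
    pst[:, 0] = 0.0
    pst[:, C - 1] = 1.0
    for k, sp in enumerate(species):
        pst[k, scheme.max_class(sp) - 1] = 1.0
    S = psv * pstpr * pst
    G = psv * pstpr * (1 - pst)
    R = psv * (1 - pstpr)
    return td.AnnualRates(species, scheme, S, G, R)


@pytest.fixture(scope="session")
def small_fit(scheme):
    """One quick real fit shared by posterior-handling tests."""
    cfg = td.make_ogawa_like_config(1, count_scale=0.05)
    histories = td.simulate_population(cfg)
    tallies = td.tally_transitions(histories, scheme)
    mc = td.ModelConfig.scaled(100, n_chains=2, seed=3)
    draws = td.sample_posterior(tallies, scheme, mc)
    return cfg, tallies, draws
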