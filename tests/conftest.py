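import numpy as np
import pandas as pd
import pytest

import assemblage as A


@pytest.fixture
def small_tree():
    return A.read_tree("((A:1,B:1)n1:1,C:2)root;")


TRAIT_TABLE_CSV = """taxon,voltinism,life_span,exoskeleton,body_shape,respiration,bmwp,body_size,flight_capacity,shelter,reophily,microhabitat,trophic_position
Baetis,1,short,soft,fusiform,gill,4,2,1,none,fast,stone,grazer
Chimarra,2,long,hard,flattened,tegument,8,3,2,case,slow,litter,predator
"""

TRAIT_META_CSV = """trait,kind,group
voltinism,ordinal,other
life_span,nominal,other
exoskeleton,nominal,other
body_shape,nominal,other
respiration,nominal,beta
bmwp,quantitative,beta
body_size,ordinal,other
flight_capacity,ordinal,other
shelter,nominal,other
reophily,nominal,alpha
microhabitat,nominal,alpha
trophic_position,nominal,alpha
"""


@pytest.fixture
def trait_table_12():
    return A.read_trait_table(TRAIT_TABLE_CSV, TRAIT_META_CSV)


@pytest.fixture(scope="session")
def sim_tree():
    return A.simulate_tree(60, seed=1)


@pytest.fixture(scope="session")
def sim_traits(sim_tree):
    return A.simulate_traits(sim_tree, seed=1)


@pytest.fixture(scope="session")
def sim_community(sim_traits):
    return A.simulate_metacommunity(sim_traits, A.ScenarioSpec(scenario="neutral", seed=1))


@pytest.fixture(scope="session")
def sim_phylo_dist(sim_tree):
    return A.cophenetic_distance(sim_tree)


def random_trait_table(rng: np.random.Generator, n_taxa: int, n_traits: int,
                       missing_rate: float = 0.0) -> "A.TraitTable":
    """Random mixed-kind trait table used by several property tests."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    kinds, data = {}, {}
    for j in range(n_traits):
        name = f"tr{j}"
        kind = ("nominal", "ordinal", "quantitative")[j % 3]
        kinds[name] = kind
        if kind == "nominal":
            col = rng.choice(list("abc"), size=n_taxa).astype(object)
        elif kind == "ordinal":
            col = rng.integers(1, 5, size=n_taxa).astype(float).astype(object)
        else:
            col = rng.normal(size=n_taxa).astype(object)
        if missing_rate > 0:
            mask = rng.random(n_taxa) < missing_rate
            col[mask] = np.nan
        data[name] = col
    df = pd.DataFrame(data, index=taxa)
    return A.TraitTable(
        data=df,
        kinds=pd.Series(kinds),
        groups=pd.Series("other", index=list(kinds)),
    )
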