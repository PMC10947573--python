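import numpy as np
import pandas as pd
import pytest

from firetraits.community import CoverTable
from firetraits.phylo import Phylogeny
from firetraits.synth import simulate_tree


@pytest.fixture(scope="session")
def star5() -> Phylogeny:
    return Phylogeny.from_newick("(a:1,b:1,c:1,d:1,e:1);")


@pytest.fixture(scope="session")
def tree8() -> Phylogeny:
    """Random 8-tip ultrametric tree, fixed seed."""
    return simulate_tree(8, 13)


@pytest.fixture(scope="session")
def tree20() -> Phylogeny:
    return simulate_tree(20, 21)


@pytest.fixture()
def small_cover() -> CoverTable:
    species = ["ga_s1", "ga_s2", "gb_s1", "gb_s2"]
    mat = pd.DataFrame(
        [[10.0, 10.0, 5.0, 0.0],
         [0.0, 20.0, 10.0, 10.0],
         [5.0, 5.0, 5.0, 5.0]],
        index=["p1", "p2", "p3"],
        columns=species,
    )
    tax = pd.DataFrame(
        {
            "genus": ["ga", "ga", "gb", "gb"],
            "family": ["fa", "fa", "fb", "fb"],
            "functional_group": ["forb", "forb", "grass", "grass"],
        },
        index=pd.Index(species, name="species"),
    )
    return CoverTable(matrix=mat, taxonomy=tax)


def make_traits(records) -> pd.DataFrame:
    """records: (plot, species, n_mass, sla) -> derived-style trait table."""
    rows = []
    for i, (plot, sp, n_mass, sla) in enumerate(records):
        rows.append(
            {
                "plot": plot, "species": sp, "individual": i,
                "percent_n": n_mass / 10.0, "percent_c": 45.0, "sla": sla,
                "n_mass": n_mass, "n_area": n_mass / sla,
                "cn_ratio": 45.0 / (n_mass / 10.0),
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
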