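import numpy as np
import pandas as pd
import pytest

from pathbench.io import GeneSet, PathwayNetwork
from pathbench.simulate import DATABASES, SimulationConfig, make_databases, simulate_expression


@pytest.fixture
def toy_ranked() -> pd.Series:
    return pd.Series({"g1": 4.0, "g2": 3.0, "g3": 2.0, "g4": 1.0})


@pytest.fixture
def toy_gene_sets() -> list[GeneSet]:
    return [
        GeneSet("kegg:hsa1", "first", "kegg", frozenset({"A", "B", "C"})),
        GeneSet("kegg:hsa2", "second", "kegg", frozenset({"C", "D"})),
        GeneSet("reactome:R1", "third", "reactome", frozenset({"A", "E", "F", "G"})),
    ]


@pytest.fixture
def toy_network() -> PathwayNetwork:
    return PathwayNetwork(
        pathway_id="kegg:net",
        database="kegg",
        nodes=frozenset({"A", "B", "C"}),
        edges=frozenset({("A", "B", "activation"), ("B", "C", "inhibition")}),
    )


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=11,
        n_genes=600,
        n_pathways_per_db=(6, 8, 7),
        pathway_size_range=(12, 25),
        n_analog_classes=3,
        n_super_classes=2,
        n_samples_per_group=40,
    )


@pytest.fixture(scope="session")
def small_resource(small_config):
    return make_databases(small_config)


@pytest.fixture(scope="session")
def small_study(small_config, small_resource):
    """Expression + labels + subtypes for the small synthetic study."""
    return simulate_expression(small_config, small_resource)


def random_gene_sets(rng: np.random.Generator, n_sets: int, max_genes: int = 50,
                     database: str = "kegg") -> list[GeneSet]:
    pool = [f"G{i:04d}" for i in range(400)]
    sets = []
    for i in range(n_sets):
        size = int(rng.integers(1, max_genes + 1))
        genes = rng.choice(pool, size=size, replace=False)
        sets.append(GeneSet(f"{database}:S{i:03d}", f"set {i}", database, frozenset(genes)))
    return sets
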