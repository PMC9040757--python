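import numpy as np
import pandas as pd
import pytest

from rhizodyn.core_data import CommunityTable, SampleMetadata, TaxonomyMap
from rhizodyn.synthetic_data import SimConfig, generate_experiment


@pytest.fixture
def small_counts() -> CommunityTable:
    df = pd.DataFrame(
        [[5, 3, 2], [1, 0, 9], [4, 4, 2]],
        index=["s1", "s2", "s3"],
        columns=["t1", "t2", "t3"],
    )
    return CommunityTable(df, kingdom="bacteria", level="ASV")


@pytest.fixture
def simple_metadata() -> SampleMetadata:
    df = pd.DataFrame(
        {
            "field": "DEMO",
            "management": "NK",
            "plot": "NK-1",
            "genotype": ["B73", "B73", "none"],
            "compartment": ["root", "root", "soil"],
            "stage": ["vegetative", "reproductive", "unplanted"],
        },
        index=["s1", "s2", "s3"],
    )
    return SampleMetadata(df)


@pytest.fixture
def simple_taxonomy() -> TaxonomyMap:
    df = pd.DataFrame(
        {"kingdom": "bacteria", "phylum": ["p1", "p1", "p2"]},
        index=pd.Index(["t1", "t2", "t3"], name="taxon_id"),
    )
    return TaxonomyMap(df)


def tiny_config(seed: int = 0, **overrides) -> SimConfig:
    """A fast single-kingdom experiment used across test modules."""
    defaults = dict(
        kingdoms=("bacteria",),
        n_taxa=80,
        n_phyla=8,
        plots_per_management={"NK": 1, "NPK": 1, "CONMIN": 1, "BIODYN": 1},
        genotypes=("B73",),
        n_replicates=3,
        n_unplanted_per_plot=3,
        n_soil_per_plot_stage=2,
        stable_core_size=15,
        n_compounds=4,
        n_linked_taxa=1,
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_experiment():
    return generate_experiment(tiny_config(seed=11))
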