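import numpy as np
import pandas as pd
import pytest

from skindyn.data_io import CountTable, SampleMetadata, TaxonomyTable
from skindyn.synthetic_cohort import CohortConfig, simulate_cohort


@pytest.fixture
def tiny_counts() -> CountTable:
    return CountTable(
        taxa=["tA", "tB", "tC"],
        samples=["s1", "s2", "s3", "s4"],
        counts=np.array([
            [10, 0, 5, 1],
            [5, 10, 0, 1],
            [0, 5, 10, 8],
        ]),
    )


@pytest.fixture
def tiny_metadata() -> SampleMetadata:
    df = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "individual": ["i1", "i1", "i2", "i2"],
            "household": ["h1", "h1", "h2", "h2"],
            "site": ["forehead"] * 4,
            "season": [1, 2, 1, 2],
            "occupancy": [2, 2, 1, 1],
            "age_group": ["adult"] * 4,
            "gender": ["F", "F", "M", "M"],
            "batch": ["B1", "B2", "B1", "B2"],
        }
    ).set_index("sample_id")
    return SampleMetadata(df)


@pytest.fixture
def tiny_taxonomy() -> TaxonomyTable:
    df = pd.DataFrame(
        {
            "kingdom": "Bacteria", "phylum": "p", "class": "c",
            "order": "o", "family": "f",
            "genus": ["g1", "g1", "g2"],
        },
        index=pd.Index(["tA", "tB", "tC"], name="taxon_id"),
    )
    return TaxonomyTable(df)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structurally complete cohort shared across tests."""
    config = CohortConfig(
        occupancies=(1, 2, 3), n_taxa=40, median_reads=2000,
        n_genera=8, n_contaminants=2, seed=42,
    )
    return config, simulate_cohort(config)
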