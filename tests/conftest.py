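import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from vivovitro.synthetic_data import SimulationConfig, generate_study
from vivovitro.tables_io import AbundanceTable

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_table(counts, taxa, samples):
    """Build an AbundanceTable from a nested list and (phylum, genus) taxa."""
    return AbundanceTable(
        pd.DataFrame(
            np.asarray(counts, dtype=np.int64),
            index=pd.MultiIndex.from_tuples(taxa, names=["phylum", "genus"]),
            columns=samples,
        )
    )


@pytest.fixture
def toy_table():
    return make_table(
        [[2, 10], [3, 20], [5, 70]],
        [("Firmicutes", "Roseburia"), ("Firmicutes", "Blautia"), ("Bacteroidetes", "Bacteroides")],
        ["s1", "s2"],
    )


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic study, shared across tests."""
    bundle, truth = generate_study(SimulationConfig(seed=1))
    return bundle, truth
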