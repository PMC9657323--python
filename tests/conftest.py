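import numpy as np
import pandas as pd
import pytest

from ruminant_ghg.community import CountTable, RANKS
from ruminant_ghg.synthetic import SyntheticSpec, default_metadata


@pytest.fixture
def rng():
    return np.random.default_rng(20210501)


@pytest.fixture
def metadata():
    return default_metadata()


@pytest.fixture
def spec():
    return SyntheticSpec(seed=7)


@pytest.fixture
def small_table():
    """4 features x 4 samples, two phyla, known margins."""
    counts = pd.DataFrame(
        {
            "s1": [10, 20, 30, 40],
            "s2": [5, 5, 45, 45],
            "s3": [25, 25, 25, 25],
            "s4": [0, 10, 60, 30],
        },
        index=["f1", "f2", "f3", "f4"],
    )
    lineage = pd.DataFrame(
        {
            "domain": ["Bacteria"] * 4,
            "phylum": ["Firmicutes", "Firmicutes", "Bacteroidetes", "Bacteroidetes"],
            "class": ["c"] * 4,
            "order": ["o"] * 4,
            "family": ["f"] * 4,
            "genus": ["g1", "g2", "g3", "g4"],
        },
        index=["f1", "f2", "f3", "f4"],
    )
    assert list(lineage.columns) == list(RANKS)
    return CountTable(counts, lineage)
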