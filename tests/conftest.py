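import numpy as np
import pandas as pd
import pytest

from ssdkit.landscape import Landscape, OTUTable


@pytest.fixture
def tiny_table() -> OTUTable:
    """3 species x 4 samples with hand-checkable structure."""
    counts = np.array(
        [
            [10, 0, 5, 5],   # sp1: in 1 of 2 A-samples, both B-samples
            [20, 30, 0, 0],  # sp2: A only
            [20, 20, 45, 45],  # sp3: everywhere
        ]
    )
    return OTUTable(["sp1", "sp2", "sp3"], ["a1", "a2", "b1", "b2"], counts)


@pytest.fixture
def tiny_landscape(tiny_table) -> Landscape:
    return Landscape(
        table=tiny_table,
        habitat_a="A",
        habitat_b="B",
        idx_a=np.array([0, 1]),
        idx_b=np.array([2, 3]),
    )


@pytest.fixture
def tiny_metadata(tiny_table) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": tiny_table.sample_ids,
            "habitat": ["A", "A", "B", "B"],
            "site": "gut",
        }
    )


def make_landscape(counts, m, habitat_a="A", habitat_b="B") -> Landscape:
    counts = np.asarray(counts)
    ns, total = counts.shape
    table = OTUTable(
        [f"sp{i}" for i in range(1, ns + 1)],
        [f"s{j}" for j in range(1, total + 1)],
        counts,
    )
    return Landscape(
        table=table,
        habitat_a=habitat_a,
        habitat_b=habitat_b,
        idx_a=np.arange(m),
        idx_b=np.arange(m, total),
    )
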