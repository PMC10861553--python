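import numpy as np
import pandas as pd
import pytest

from airway_profiler.ko_profiles import KOProfileMatrix


@pytest.fixture
def toy_ko_matrix() -> KOProfileMatrix:
    """10 isolates x 6 KOs with a clear 2-cluster structure by hand."""
    vals = np.array([
        # K1 K2 K3 K4 K5 K6
        [1, 1, 0, 0, 1, 0],
        [1, 1, 0, 0, 0, 1],
        [1, 1, 0, 0, 1, 1],
        [1, 1, 0, 0, 0, 0],
        [1, 1, 0, 0, 1, 0],
        [0, 0, 1, 1, 1, 0],
        [0, 0, 1, 1, 0, 1],
        [0, 0, 1, 1, 1, 1],
        [0, 0, 1, 1, 0, 0],
        [0, 0, 1, 1, 1, 0],
    ], dtype=np.uint8)
    return KOProfileMatrix(
        [f"iso{i}" for i in range(10)],
        [f"K0000{j}" for j in range(1, 7)],
        vals,
    )


@pytest.fixture
def toy_labels(toy_ko_matrix):
    """Hand-built cluster assignment matching the toy matrix blocks."""
    from airway_profiler.ko_profiles import ClusterAssignment

    return ClusterAssignment({iso: (1 if i < 5 else 2)
                              for i, iso in enumerate(toy_ko_matrix.isolate_ids)})


@pytest.fixture
def small_otu_table():
    counts = pd.DataFrame(
        [[50, 30, 15, 5], [40, 40, 10, 10], [70, 10, 10, 10], [25, 25, 25, 25]],
        index=["s1", "s2", "s3", "s4"],
        columns=["otu1", "otu2", "otu3", "otu4"],
    )
    taxonomy = pd.DataFrame(
        {"kingdom": "Bacteria",
         "genus": ["Streptococcus", "Veillonella", "Prevotella", "Haemophilus"]},
        index=counts.columns,
    )
    from airway_profiler.community_prep import OTUTable

    return OTUTable(counts, taxonomy)
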