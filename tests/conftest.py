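import numpy as np
import pandas as pd
import pytest

from phylloplane import AsvTable, CommunitySimConfig, StudyDesign, simulate_community


@pytest.fixture(scope="session")
def small_community():
    """Scaled-down seeded community: 6 sites x 2 rounds, 60 taxa."""
    design = StudyDesign(rounds=2)
    cfg = CommunitySimConfig(n_taxa=60, seed=11)
    counts, taxonomy, metadata, truth = simulate_community(design, cfg)
    return counts, taxonomy, metadata, truth


@pytest.fixture(scope="session")
def small_table(small_community):
    counts, taxonomy, _, _ = small_community
    return AsvTable(counts=counts, taxonomy=taxonomy)


@pytest.fixture
def toy_table():
    """Hand-sized count table with a chloroplast contaminant."""
    counts = pd.DataFrame(
        {
            "s1": [9, 99, 0, 5],
            "s2": [10, 0, 3, 2],
            "s3": [0, 0, 0, 400],
        },
        index=["t1", "t2", "t3", "chl"],
    )
    taxonomy = pd.DataFrame(
        {
            "kingdom": ["Bacteria"] * 4,
            "phylum": ["P1", "P1", "P2", "Cyanobacteria"],
            "class": ["C1", "C1", "C2", "Oxyphotobacteria"],
            "order": ["O1", "O2", "O3", "Chloroplast"],
            "family": ["F1", "F2", "F3", "Chloroplast"],
            "genus": ["G1", "G2", "G3", "Chloroplast"],
        },
        index=["t1", "t2", "t3", "chl"],
    )
    return AsvTable(counts=counts, taxonomy=taxonomy)


def euclidean_distance_frame(points: np.ndarray, prefix: str = "s") -> pd.DataFrame:
    from scipy.spatial.distance import cdist

    ids = [f"{prefix}{i}" for i in range(len(points))]
    return pd.DataFrame(cdist(points, points), index=ids, columns=ids)
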