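import numpy as np
import pytest

import alra


@pytest.fixture(scope="session")
def small_sim():
    """A 100-cell x 80-gene, 3-type multinomial dataset with ground truth."""
    bulk = alra.synth_bulk(3, 80, zero_fraction=0.2, overlap=0.5, seed=20)
    profiles = alra.to_probabilities(bulk)
    return alra.simulate_cells(profiles, 100, seed=21), profiles


@pytest.fixture(scope="session")
def medium_sim():
    """A 400-cell x 600-gene, 4-type dataset for pipeline-level checks."""
    bulk = alra.synth_bulk(4, 600, zero_fraction=0.3, overlap=0.5, seed=5)
    profiles = alra.to_probabilities(bulk)
    return alra.simulate_cells(
        profiles, 400, depths={"median": 2000, "sigma": 0.5}, seed=8
    ), profiles


@pytest.fixture()
def tiny_counts():
    """3 cells x 2 genes with explicit ids."""
    return alra.CountMatrix(
        values=np.array([[1, 0], [3, 2], [0, 5]]),
        cell_ids=["AAA", "BBB", "CCC"],
        gene_ids=["G1", "G2"],
    )
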