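import numpy as np
import pytest

from strainvar.orthomap import SegmentMatrix
from strainvar.simulate import SimConfig, simulate_strains


@pytest.fixture(scope="session")
def small_sim():
    """A 40-gene collection on the default 9-taxon tree."""
    return simulate_strains(SimConfig(n_genes=40, seed=11))


@pytest.fixture(scope="session")
def star_sim():
    """Five strains at 5% divergence from a common reference ancestor."""
    tree = "(A:0.05,B:0.05,C:0.05,D:0.05,E:0.05);"
    return simulate_strains(SimConfig(n_genes=60, strain_tree=tree, seed=7))


def make_matrix(rows: dict[str, str], seg_id: str = "seg") -> SegmentMatrix:
    return SegmentMatrix(seg_id, list(rows), list(rows.values()))


@pytest.fixture
def rng():
    return np.random.default_rng(123)
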