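import numpy as np
import pytest

from sharedmap import ArealDataset, build_lattice_adjacency


@pytest.fixture
def lattice_2x2():
    return build_lattice_adjacency(2, 2, "rook")


@pytest.fixture
def path3():
    """3-node path graph a-b-c."""
    from sharedmap.spatial import graph_from_id_lists

    return graph_from_id_lists(
        ["a", "b", "c"], {"a": ["b"], "b": ["a", "c"], "c": ["b"]}
    )


@pytest.fixture
def small_dataset(lattice_2x2):
    """Two-outcome dataset on the 2x2 lattice with one covariate."""
    rng = np.random.default_rng(42)
    O = rng.poisson(5.0, size=(4, 2))
    E = np.full((4, 2), 5.0)
    X = rng.standard_normal((4, 1))
    return ArealDataset(lattice_2x2, O, E, X, ["x1"])
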