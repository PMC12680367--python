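import numpy as np
import pytest

from fibranet.ecm_network import FibreNetwork
from fibranet.focal_adhesion import CatchBondParams


@pytest.fixture
def catch_params():
    return CatchBondParams()


@pytest.fixture
def two_node_network():
    """One pinned crosslink at the origin, one free at distance 1.5, L0=1."""
    return FibreNetwork(
        positions=[[0.0, 0.0], [1.5, 0.0]],
        fibres=[[0, 1]],
        rest_lengths=[1.0],
        pinned=[True, False],
        E_t=1e5, area=0.01, compression_factor=0.1, eta=100.0,
    )


@pytest.fixture
def small_random_network():
    """Small irregular spring network for gradient/force checks."""
    rng = np.random.default_rng(7)
    pos = rng.random((8, 2)) * 10.0
    fibres = [[0, 1], [1, 2], [2, 3], [3, 4], [4, 5], [5, 6], [6, 7],
              [0, 3], [2, 5], [1, 6]]
    pos_arr = np.asarray(pos)
    lengths = np.linalg.norm(pos_arr[[f[1] for f in fibres]]
                             - pos_arr[[f[0] for f in fibres]], axis=1)
    # rest lengths deliberately off the current geometry: network under load
    rest = lengths * rng.uniform(0.8, 1.2, size=len(fibres))
    return FibreNetwork(positions=pos, fibres=fibres, rest_lengths=rest,
                        pinned=np.zeros(8, bool), E_t=1e6, area=0.01,
                        eta=100.0)


def star_network(directions, rest_lengths=None):
    """Crosslink 0 at the origin with neighbours along given unit directions."""
    directions = np.asarray(directions, dtype=float)
    pos = np.vstack([[0.0, 0.0], directions])
    fibres = [[0, i + 1] for i in range(len(directions))]
    if rest_lengths is None:
        rest_lengths = np.linalg.norm(directions, axis=1)
    return FibreNetwork(positions=pos, fibres=fibres,
                        rest_lengths=rest_lengths,
                        pinned=np.zeros(len(pos), bool))
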