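import numpy as np
import pytest

from pdacsim import VCBMParams, init_hexagonal_tissue, seed_tumour


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def hex_tissue():
    """Small all-healthy hexagonal tissue."""
    return init_hexagonal_tissue(9, 9, 1.0)


@pytest.fixture
def seeded_tissue(hex_tissue):
    return seed_tumour(hex_tissue)


@pytest.fixture
def params():
    return VCBMParams()


def make_pair_tissue(distance: float, rest: float = 1.0):
    """Two connected cells plus two distant anchor cells (so the
    triangulation stays valid), for single-spring mechanics checks."""
    from pdacsim.lattice import HEALTHY, Tissue

    pos = np.array([[0.0, 0.0], [distance, 0.0]])
    n = 2
    t = Tissue(
        ids=np.arange(n, dtype=np.int64),
        positions=pos,
        cell_type=np.full(n, HEALTHY, dtype=np.int8),
        age=np.zeros(n, dtype=np.int64),
        cooldown=np.zeros(n, dtype=np.int64),
        maturity=np.ones(n),
        disintegration_left=np.zeros(n, dtype=np.int64),
        disintegration_total=np.zeros(n, dtype=np.int64),
        voronoi_area=np.ones(n),
        edges=np.array([[0, 1]], dtype=np.int64),
        rest_length=np.array([rest]),
        rest_decrement=np.zeros(1),
        bounds=(-100.0, 100.0, -100.0, 100.0),
    )
    return t
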