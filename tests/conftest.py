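import numpy as np
import pytest

from multiweb.net import MultiplexNet


def make_net(n, edges):
    """Build a small net from (i, j, layer) index triples."""
    ids = tuple(chr(ord("a") + i) for i in range(n))
    mats = {c: np.zeros((n, n), dtype=np.int8) for c in "TPN"}
    for i, j, code in edges:
        mats[code][i, j] = 1
    return MultiplexNet(ids, mats["T"], mats["P"], mats["N"])


@pytest.fixture
def tiny_net():
    # a eats b, b negatively affects a, a facilitates c
    return make_net(3, [(0, 1, "T"), (1, 0, "N"), (0, 2, "P")])


@pytest.fixture
def random_net():
    rng = np.random.default_rng(42)
    n = 12
    ids = tuple(f"s{i}" for i in range(n))
    mats = []
    for dens in (0.25, 0.05, 0.3):
        m = (rng.random((n, n)) < dens).astype(np.int8)
        np.fill_diagonal(m, 0)
        mats.append(m)
    return MultiplexNet(ids, *mats)
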