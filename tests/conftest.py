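import numpy as np
import pytest

import raftnet as rn


@pytest.fixture(scope="session")
def fig1_network():
    return rn.bundled_network("fig1")


@pytest.fixture(scope="session")
def fig5_network():
    return rn.bundled_network("fig5")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_component(
    name="X",
    radius=0,
    states=("inactive", "active"),
    prefs=(1, 1),
    count=1,
    mobility=0.5,
):
    return rn.ComponentType(
        name=name,
        radius=radius,
        states=tuple(states),
        boundary_pref=dict(zip(states, prefs)),
        count=count,
        mobility=mobility,
    )


@pytest.fixture()
def small_mixed_state():
    """12x12 lattice with a few small inclusions of mixed preference."""
    net = rn.NetworkSpec(
        components=[
            make_component("U", radius=0, states=("s",), prefs=(1,), count=2),
            make_component("D", radius=1, states=("s",), prefs=(-1,), count=2),
        ],
        rules=[],
        target="",
    )
    return rn.init_lattice(12, 0.2, net, seed=5)
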