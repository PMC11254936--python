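import numpy as np
import pytest

import netsde as ns


@pytest.fixture(scope="session")
def small_topo():
    return ns.generate_network("binary", n=6, density=0.3, seed=11)


@pytest.fixture(scope="session")
def lc_spec():
    return ns.make_model("linear_cubic_test")


@pytest.fixture(scope="session")
def lc_series(lc_spec, small_topo):
    rng = np.random.default_rng(0)
    x0 = rng.normal(size=(small_topo.n, 3))
    return ns.simulate(lc_spec, small_topo, x0, steps=800, dt=0.01, seed=5)


class StubNet:
    """Callable standing in for a trained map in component-model tests."""

    def __init__(self, fn):
        self.fn = fn

    def __call__(self, x):
        return self.fn(np.asarray(x, dtype=float))


@pytest.fixture
def stub_model():
    """ComponentModel whose components are explicit functions, not trained nets."""

    def build(f=None, g=None, phi=None, d=3):
        zero = lambda x: np.zeros((x.shape[0], d))
        return ns.ComponentModel(
            d=d,
            f_net=StubNet(f or zero),
            g_nets={None: StubNet(g or (lambda z: np.zeros((z.shape[0], d))))},
            phi_net=StubNet(phi or (lambda x: np.full((x.shape[0], d), -30.0))),
            norm_mean=np.zeros(d),
            norm_std=np.ones(d),
        )

    return build
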