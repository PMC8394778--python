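import numpy as np
import pytest

from osteochemo import cohort, engine, regimens


@pytest.fixture(scope="session")
def suite():
    """The three synthetic cluster scenarios (deterministic)."""
    return cohort.make_cluster_suite(seed=0)


@pytest.fixture(scope="session")
def cluster1(suite):
    return suite[1]


@pytest.fixture(scope="session")
def cluster3(suite):
    return suite[3]


@pytest.fixture(scope="session")
def map_regimen():
    return regimens.build_map()


@pytest.fixture(scope="session")
def map_trajectories(suite, map_regimen):
    """Two-cycle MAP trajectories from the large-tumor state of each cluster."""
    out = {}
    for cid, sc in suite.items():
        out[cid] = engine.simulate(
            sc.steady_state, sc.params, sc.chemo, map_regimen, horizon=85.0,
            output_dt=0.1)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
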