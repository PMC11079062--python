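import pytest

from udsnet import ModelParams, simulate


@pytest.fixture(scope="session")
def default_params():
    return ModelParams()


@pytest.fixture(scope="session")
def uds_trace(default_params):
    """One 200 s isolated-network trajectory showing UDS."""
    return simulate(default_params, 200.0, seed=1, record_every=25,
                    burn_in=5.0)


@pytest.fixture(scope="session")
def surrogate_cell():
    """One rendered surrogate cell (V_m + LFP, 300 s, mid-grid truth)."""
    from udsnet.surrogate import make_cell_dataset
    return make_cell_dataset([(0.20, 1.08)], duration=300.0, seed=11)[0]
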