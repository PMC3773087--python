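import pytest

from electroflux import SweepConfig, make_fixture_suite, make_toy_model, optimal_growth


@pytest.fixture(scope="session")
def config():
    return SweepConfig()


@pytest.fixture(scope="session")
def wild():
    """Default wild-type toy model with its ground truth."""
    return make_toy_model()


@pytest.fixture(scope="session")
def wild_vgr_max(wild, config):
    model, _ = wild
    return optimal_growth(model, config)


@pytest.fixture(scope="session")
def suite():
    return make_fixture_suite()
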