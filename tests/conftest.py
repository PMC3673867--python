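import pytest

from voltflux import fixtures


@pytest.fixture
def fig5():
    return fixtures.figure5_network()


@pytest.fixture
def mini():
    return fixtures.mini_geobacter()


# Hand-derived optima for the mini fixture at the default conditions
# (uptake 18, NGAM 0.45); derivation in the fixture docstring.
MINI_MAX_GROWTH = 143.55 / 120  # 1.19625 1/h
MINI_MET_CEILING = 72.0 - 0.45 / 2  # 71.775 mmol/gDW/h drain flux
MINI_DET_CEILING = 72.0  # mmol/gDW/h drain flux


@pytest.fixture
def mini_truth():
    return {
        "max_growth": MINI_MAX_GROWTH,
        "met_ceiling": MINI_MET_CEILING,
        "det_ceiling": MINI_DET_CEILING,
    }
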