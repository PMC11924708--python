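import numpy as np
import pytest

from samgsd.design import DesignConfig, build_gs_design
from samgsd.fixtures import DELTA, MAP_EM_MIXTURE, MARGIN_M, THETA_H_HAT
from samgsd.historical import HistoricalStudy
from samgsd.mixture import BetaMixture


@pytest.fixture(scope="session")
def map_em():
    """Published MAP-EM approximation used as the worked-example fixture."""
    return MAP_EM_MIXTURE


@pytest.fixture(scope="session")
def four_studies():
    return [
        HistoricalStudy(204, 30),
        HistoricalStudy(220, 20),
        HistoricalStudy(499, 14),
        HistoricalStudy(60, 10),
    ]


@pytest.fixture(scope="session")
def example_design():
    """The worked example's 3-look binding HSD(-4)/HSD(-2) design."""
    return build_gs_design(DesignConfig())


@pytest.fixture(scope="session")
def example_constants():
    return {"theta_h_hat": THETA_H_HAT, "delta": DELTA, "margin_m": MARGIN_M}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def uniform():
    return BetaMixture([(1.0, 1.0)], [1.0])
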