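import numpy as np
import pytest

from pdlrom import builtin_test_table, campaign_pulses
from pdlrom.reference import (campaign_fit_params, individual_fit_params,
                              reference_hyperfoam)


@pytest.fixture(scope="session")
def protocols():
    return builtin_test_table()


@pytest.fixture(scope="session")
def truth():
    """Joint-fit reference parameters used as generating truth."""
    return campaign_fit_params()


@pytest.fixture(scope="session")
def hyper():
    return reference_hyperfoam()


@pytest.fixture(scope="session")
def pulses_by_test(protocols):
    return {p.test_id: campaign_pulses(protocols, p.test_id)
            for p in protocols}


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
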