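import numpy as np
import pytest

from betarec.task_design import DesignConfig, build_session


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def default_criteria():
    return (1.2, 0.6, 0.0, -0.6, -1.2)


@pytest.fixture(scope="session")
def session_design():
    """One default session design shared across tests (seed-fixed)."""
    return build_session(DesignConfig(), rng=123)


@pytest.fixture(scope="session")
def forced_design():
    """Session design with the published targeted-match totals (36/33)."""
    return build_session(
        DesignConfig(force_targeted_match={"beta": 36, "random": 33}), rng=123
    )
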