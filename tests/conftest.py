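import numpy as np
import pytest

from schemabg import ParameterSet, run_session


@pytest.fixture(scope="session")
def params():
    return ParameterSet()


@pytest.fixture(scope="session")
def default_session(params):
    """One default-parameter session, reused across read-only tests."""
    return run_session(params, seed=101)


@pytest.fixture(scope="session")
def traced_session(params):
    """One default session with per-cycle traces."""
    return run_session(params, seed=202, record_traces=True)


@pytest.fixture(scope="session")
def traced_sessions(params):
    """A small pool of traced sessions for ERP statistics."""
    ss = np.random.SeedSequence(303)
    return [run_session(params, seed=c, record_traces=True) for c in ss.spawn(8)]
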