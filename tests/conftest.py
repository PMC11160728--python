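import numpy as np
import pytest

from extruderquant.synthetic import TraceSimParams, gen_traces


@pytest.fixture(scope="session")
def noloop_traces():
    """Ideal-chain traces without planted loops (shared across tests)."""
    return gen_traces(TraceSimParams(n_traces=400, seed=101))


@pytest.fixture(scope="session")
def looped_traces():
    """Traces with one planted loop over bins [10, 60) at 0.3 compaction."""
    return gen_traces(TraceSimParams(n_traces=400, loops=[(10, 60, 0.3)], seed=102))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
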