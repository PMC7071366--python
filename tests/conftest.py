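import pytest

from cinet.experiments import run_all

#: one fixed seed for the shared desk-scale protocol run
PROTOCOL_SEED = 7


@pytest.fixture(scope="session")
def protocol_results():
    """One desk-scale (5 networks x 50 samples) run of all seven experiment
    sets for both center types, shared across the acceptance tests."""
    return run_all(seed=PROTOCOL_SEED)
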