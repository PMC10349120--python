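import numpy as np
import pytest

import betastate as bs


@pytest.fixture(scope="session")
def sched_9010():
    """One validated 90/10 Exp-III-style schedule shared across tests."""
    spec = bs.SessionSpec.from_style("90/10", "III", seed=11)
    return bs.assemble_schedule(spec)


@pytest.fixture(scope="session")
def sched_7525():
    spec = bs.SessionSpec.from_style("75/25", "III", seed=21)
    return bs.assemble_schedule(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
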