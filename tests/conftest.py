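import numpy as np
import pytest
from hypothesis import settings

from rmdyn import load_preset, stability_boundary

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def esp():
    return load_preset("esp1396i")


@pytest.fixture(scope="session")
def ahdi():
    return load_preset("ahdi")


@pytest.fixture(scope="session")
def ecorv():
    return load_preset("ecorv")


@pytest.fixture(scope="session")
def boundaries(esp, ahdi, ecorv):
    """Fold boundaries for the three systems, computed once per session."""
    return {
        "esp1396i": stability_boundary(esp.internal),
        "ahdi": stability_boundary(ahdi.internal),
        "ecorv": stability_boundary(ecorv.internal),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
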