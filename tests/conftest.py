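import numpy as np
import pytest

from hbodc.protocol_sim import Protocol, simulate
from hbodc.synthetic_data import nominal_protocol, nominal_scheme


@pytest.fixture(scope="session")
def protocol():
    return nominal_protocol()


@pytest.fixture(scope="session")
def traj_minimalist(protocol):
    return simulate(nominal_scheme("minimalist"), protocol)


@pytest.fixture(scope="session")
def traj_perutz(protocol):
    return simulate(nominal_scheme("perutz"), protocol)


@pytest.fixture(scope="session")
def traj_mwc(protocol):
    return simulate(nominal_scheme("mwc"), protocol)


@pytest.fixture(scope="session")
def short_protocol():
    """A compressed deox/reox cycle for fitting tests (faster turnover)."""
    return Protocol.default(
        t_end=600.0, dt=1.0, t_respiration_on=20.0, t_open=420.0
    )


# faster oxidase so the short protocol still reaches anaerobiosis
SHORT_KCAT = {"k_cat": 15.0}
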