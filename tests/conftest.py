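import numpy as np
import pytest

from stgscape import integrate, load_parameter_table
from stgscape.stg_model import default_kinetics


@pytest.fixture(scope="session")
def table():
    return load_parameter_table()


@pytest.fixture(scope="session")
def kinetics():
    return default_kinetics()


@pytest.fixture(scope="session")
def trace_a(table):
    """Model (a) under the standard scoring protocol (20 s, drop 10 s)."""
    return integrate(table["a"], duration=2.0e4, dt=0.1, transient=1.0e4,
                     record_currents=False)


@pytest.fixture(scope="session")
def trace_fig2_currents(table):
    """A short model-(fig2) window with all per-channel currents recorded."""
    return integrate(table["fig2"], duration=1.3e4, dt=0.1, transient=1.0e4,
                     record_currents=True)
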