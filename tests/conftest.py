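import pytest

import eemquant as eq
from eemquant.workflow import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def instrument():
    return eq.default_instrument()


@pytest.fixture(scope="session")
def noiseless_instrument():
    return eq.default_instrument().noiseless()


@pytest.fixture(scope="session")
def factorial():
    return eq.fluorophore_factorial()


@pytest.fixture(scope="session")
def seed1_run(factorial):
    """Default-noise factorial analysis at seed 1 (shared: it is the dataset
    the recovery, component-selection and independence checks all use)."""
    return run_pipeline(RunConfig(seed=1, design=factorial, components="auto",
                                  tau=0.01, k_max=8))


@pytest.fixture(scope="session")
def noiseless_run(factorial):
    """Noiseless factorial analysis with the saturation ceiling lifted: the
    ideal linear-response regime."""
    ins = eq.default_instrument().noiseless().without_saturation()
    return run_pipeline(RunConfig(seed=0, instrument=ins, design=factorial,
                                  components=3, k_max=4))
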