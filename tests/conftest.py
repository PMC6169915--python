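import numpy as np
import pytest

from iontune.models import ToyVentricularModel


@pytest.fixture()
def toy():
    return ToyVentricularModel()


@pytest.fixture(scope="session")
def paced_1hz():
    """300 beats at CL 1000 ms on the default toy model (shared)."""
    from iontune.protocols import steady_state_pacing
    model = ToyVentricularModel()
    series, trace = steady_state_pacing(model, 1000.0, 300)
    return model, series, trace


@pytest.fixture(scope="session")
def short_paced():
    """20 beats at CL 1000 ms (shared, cheap)."""
    from iontune.protocols import steady_state_pacing
    model = ToyVentricularModel()
    series, trace = steady_state_pacing(model, 1000.0, 20)
    return model, series, trace


@pytest.fixture(scope="session")
def toy_scenario_result():
    """The full end-to-end calibration run (expensive; computed once)."""
    import warnings
    from iontune.synthetic import make_toy_scenario
    scenario = make_toy_scenario()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = scenario.fit()
    return scenario, result


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
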