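import numpy as np
import pytest

from splitkinase import ParameterSet, build_basic_network, scan_signal_response


@pytest.fixture(scope="session")
def base_params():
    return ParameterSet()


@pytest.fixture(scope="session")
def basic_network():
    return build_basic_network()


@pytest.fixture(scope="session")
def default_curve(basic_network, base_params):
    """Signal-response curve at base parameters, shared across tests.

    120 grid points keep the full analysis (folds, unstable branch, slope
    refinement) to a few seconds while resolving the bistable window.
    """
    return scan_signal_response(basic_network, base_params, (0.0, 10.0), n_points=120)


@pytest.fixture(scope="session")
def monostable_curve(basic_network, base_params):
    """Curve at the weakest association rate (k1 = 0.208): monostable."""
    return scan_signal_response(
        basic_network, base_params.with_(k1=0.208), (0.0, 10.0), n_points=120
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
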