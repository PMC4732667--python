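import numpy as np
import pytest

from tadnet.network import NetworkGraph
from tadnet.neurons import build_din, build_generic_hh


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def single_din_net():
    return NetworkGraph([build_din()], [], [], seed=0, builder="manual")


@pytest.fixture(scope="session")
def single_hh_net():
    return NetworkGraph([build_generic_hh()], [], [], seed=0,
                        builder="manual")


# Expensive figure-level computations shared across acceptance tests.

@pytest.fixture(scope="session")
def start_sweep():
    """Feedback-strength sweep of the sensory-started dIN rhythm."""
    from tadnet.experiments import run_start
    return run_start(g_grid=[0.05, 0.07, 0.09, 0.11, 0.13, 0.15, 0.2],
                     seeds=(1, 2, 3), duration=1400.0)


@pytest.fixture(scope="session")
def stop_results():
    """Stop-probability grid (3 trials per cell) plus the canonical run."""
    from tadnet.experiments import run_stop
    return run_stop(n_trials=3, seed=0)


@pytest.fixture(scope="session")
def perfusion_results():
    from tadnet.experiments import run_perfusion
    return run_perfusion(duration=1200.0, seed=0)
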