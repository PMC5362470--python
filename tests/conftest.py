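import numpy as np
import pytest
from hypothesis import settings

import hccnma as h

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def hcc_network():
    return h.load_hcc_network()


@pytest.fixture(scope="session")
def small_sim():
    """A tiny simulated triangle network with survivor data, fixed seed."""
    config = h.SimulationConfig(
        treatments=["A", "B", "C"],
        d={"A": 0.0, "B": -0.4, "C": 0.3},
        tau=0.05,
        baseline_survival=(0.6, 0.4, 0.28, 0.2),
        roster=[
            h.TrialSpec("t1", ("A", "B"), (200, 200)),
            h.TrialSpec("t2", ("B", "C"), (200, 200)),
            h.TrialSpec("t3", ("A", "C"), (200, 200)),
            h.TrialSpec("t4", ("A", "B", "C"), (150, 150, 150)),
        ],
        reference="A",
    )
    return h.simulate_network(config, seed=1234)


def single_contrast_set(label, a, b, loghr, se, horizon=1):
    return h.ContrastSet(
        trial_label=label,
        baseline=b,
        contrasts=[h.LogHREstimate(label, a, b, horizon, loghr, se)],
        covariance=np.array([[se**2]]),
    )


@pytest.fixture
def make_contrast_set():
    return single_contrast_set
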