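import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from msdom import simulate as sim
from msdom.params import MSDOMParams

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


def intercept_truth_full(psi, det_day=(0.5, -0.5), det_night=(0.3, 0.5),
                         det_state4=((0.2, -0.4), (0.0, 0.4), (-0.3, 0.3))):
    """Full-model intercept-only truth hitting exact state probabilities."""
    psi = np.asarray(psi, dtype=float)
    b = np.log(psi[1:] / psi[0])
    return MSDOMParams(
        "full",
        {"day": [b[0]], "night": [b[1]], "daynight": [b[2]]},
        {s: ["intercept"] for s in ("day", "night", "daynight")},
        det_day=np.asarray(det_day), det_night=np.asarray(det_night),
        det_state4=np.asarray(det_state4),
    )


def intercept_truth_reduced(theta_day=0.0, theta_night=0.0,
                            det_day=(0.5, -0.5), det_night=(0.3, 0.5)):
    return MSDOMParams(
        "reduced",
        {"day": [theta_day], "night": [theta_night]},
        {s: ["intercept"] for s in ("day", "night")},
        det_day=np.asarray(det_day), det_night=np.asarray(det_night),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20210526)


@pytest.fixture
def small_scenario():
    return sim.ScenarioConfig(n_sites=30, n_occasions=10, seed=3)


@pytest.fixture
def tiny_history():
    """12-row 2-season history with all four states present."""
    cfg = sim.ScenarioConfig(n_sites=6, n_occasions=8, seed=1,
                             missingness_rate=0.1,
                             truth=sim.default_truth("season", "full", seed=2))
    history, latent, design = sim.simulate_state_history(cfg)
    return history, design
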