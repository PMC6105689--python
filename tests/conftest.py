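import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True)
settings.load_profile("derandomized")

from tiltnorm.model import GratingComponent, NormalizationParams
from tiltnorm.observer import (
    ObserverModel,
    SessionDesign,
    build_session,
    simulate_responses,
)


@pytest.fixture
def default_params():
    """Standard-model parameters matching the illustrative contrast-response
    figure: rmax = 50 Hz, c50 = 20% Michelson, kappa = 1."""
    return NormalizationParams()


@pytest.fixture
def target():
    return GratingComponent(0.0, 100.0, 1.5)


@pytest.fixture
def mask():
    return GratingComponent(45.0, 100.0, 3.75)


@pytest.fixture
def default_design():
    return SessionDesign()


@pytest.fixture
def repulsive_observer():
    return ObserverModel(pse_single=-1.5, pse_compound=1.5, sigma=2.0, lapse=0.02)


@pytest.fixture
def simulated_session(default_design, repulsive_observer):
    """One full 1,200-trial session from a repulsive observer, fixed seed."""
    trials = build_session(default_design, seed=101, participant_id="obs01",
                           group="td")
    return simulate_responses(trials, repulsive_observer, seed=202)


def binned(trials, condition):
    """Collapse one condition of a trial table to (levels, n, k)."""
    sub = trials[trials["condition"] == condition]
    levels = np.unique(sub["varied_orientation_deg"])
    n = np.array([(sub["varied_orientation_deg"] == lv).sum() for lv in levels],
                 dtype=float)
    k = np.array(
        [
            sub.loc[sub["varied_orientation_deg"] == lv, "response_chose_varied"].sum()
            for lv in levels
        ],
        dtype=float,
    )
    return levels.astype(float), n, k
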