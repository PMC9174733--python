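import warnings

import numpy as np
import pytest

import pentrack as pt

warnings.filterwarnings("ignore", message="ArviZ is undergoing")


@pytest.fixture(scope="session")
def pen():
    return pt.PenGeometry.default()


@pytest.fixture(scope="session")
def small_metric_table():
    """60 x 12 table with strong personality and predictability variation."""
    return pt.simulate_metric_table(pt.MetricSimConfig(
        n_individuals=60, n_units=12, v_ind=0.8, v_res=0.2,
        omega2_id=0.2151, seed=11))


@pytest.fixture(scope="session")
def short_mcmc():
    return pt.MCMCSettings(n_chains=2, n_iter=2400, burn_in=1200, thin=2,
                           seed=5)


def make_trajectory(x, y, t=None, hz=1.0, individual_id="calf_001"):
    x = np.asarray(x, dtype=float)
    if t is None:
        t = np.arange(len(x), dtype=float) / hz
    return pt.Trajectory(individual_id, t, x, np.asarray(y, dtype=float), hz)
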