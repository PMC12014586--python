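"""Shared fixtures.

The scenario fixtures run the full experimental conditions once per session
at desk scale (3 replicates, full 96 h / 72 h horizons) and are shared by the
acceptance tests.
"""

import numpy as np
import pytest

import spheroidsim as s
from spheroidsim.metrics import aggregate

REPLICATES = 10
BASE_SEED = 1


def _condition(name: str, rib: float, t_end_h: float):
    scn = s.preset(name, n_replicates=REPLICATES, t_end_hours=t_end_h)
    df = s.run_replicates(scn.params_at(rib), REPLICATES, BASE_SEED,
                          scn.t_end_min)
    return df, aggregate(df).set_index("time_min")


@pytest.fixture(scope="session")
def invasive_runs():
    """{ribose: aggregated metrics} for the invasive preset, 96 h."""
    return {rib: _condition("invasive", rib, 96.0)[1]
            for rib in (0.0, 50.0, 200.0)}


@pytest.fixture(scope="session")
def noninvasive_runs():
    """{ribose: aggregated metrics} for the non-invasive preset, 96 h."""
    return {rib: _condition("noninvasive", rib, 96.0)[1]
            for rib in (0.0, 50.0, 200.0)}


@pytest.fixture(scope="session")
def gm6001_run():
    """Aggregated metrics for the MMP-inhibited invasive preset, 0 mM, 72 h."""
    return _condition("gm6001", 0.0, 72.0)[1]


@pytest.fixture()
def rng():
    return np.random.Generator(np.random.PCG64(1234))


@pytest.fixture()
def fast_params():
    """Small, fast configuration for engine-level behavioural tests."""
    return s.ModelParams(domain_half_width=200.0, raster_n=500)
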