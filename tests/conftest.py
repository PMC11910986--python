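import numpy as np
import pandas as pd
import pytest

from ampcyto import (
    Coupling,
    EventTable,
    SimulationTruth,
    default_tcr_trajectories,
    simulate_signaling_timecourse,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240715)


@pytest.fixture
def small_table(rng):
    """50 events x 3 channels over two conditions with timepoint metadata."""
    values = rng.uniform(0, 100, size=(50, 3))
    meta = pd.DataFrame(
        {
            "condition_id": ["a"] * 25 + ["b"] * 25,
            "timepoint_min": ([0.0] * 13 + [5.0] * 12) * 2,
            "cycle_count": 1,
        }
    )
    return EventTable(values, ["ch1", "ch2", "ch3"], meta)


@pytest.fixture(scope="session")
def coupled_timecourse():
    """Small signaling timecourse: m1->m2 strongly coupled, m3 independent."""
    markers = ["m1", "m2", "m3"]
    truth = SimulationTruth(
        seed=101,
        n_cells=1500,
        trajectory_shapes=default_tcr_trajectories(markers),
        couplings=(Coupling("m1", "m2", "linear", 0.05),),
        count_scale=100.0,
    )
    return simulate_signaling_timecourse(truth)
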