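"""Shared fixtures: tiny deterministic trajectories and a reduced study fit."""

import numpy as np
import pandas as pd
import pytest

from deerseed import AnalysisConfig, DeerDispersalModel, Trajectory


def make_trajectory(animal_id="deer_t", n_fixes=100, start="2018-05-01T00:00",
                    vx=1000.0, vy=0.0, vz=0.0, z0=600.0,
                    interval_h=1.0) -> Trajectory:
    """Straight-line walk: constant velocity (vx, vy) m/h, climb vz m/h."""
    t0 = np.datetime64(start, "ns")
    step = np.timedelta64(int(interval_h * 3600 * 1e9), "ns")
    times = t0 + np.arange(n_fixes) * step
    h = np.arange(n_fixes) * interval_h
    return Trajectory(animal_id=animal_id, times=times, easting=vx * h,
                      northing=vy * h, elevation=z0 + vz * h)


@pytest.fixture
def straight_walk():
    return make_trajectory()


@pytest.fixture
def climb_walk():
    return make_trajectory(vx=100.0, vz=10.0)


@pytest.fixture(scope="session")
def small_config():
    return AnalysisConfig(rng_seed=11, n_endpoint_draws=2000,
                          n_passage_draws_per_cell=2000, n_permutations=500)


@pytest.fixture(scope="session")
def small_results(small_config):
    """One reduced-scale synthetic study, fitted once per session."""
    return DeerDispersalModel.from_synthetic(config=small_config).fit()


@pytest.fixture
def toy_samples():
    """Four dung samples for two animals across two months."""
    from deerseed import DungSample
    return [
        DungSample("s1", "a1", pd.Timestamp("2018-06-05"), 100.0,
                   {"sp_a": 13, "sp_b": 2}),
        DungSample("s2", "a1", pd.Timestamp("2018-06-15"), 50.0,
                   {"sp_a": 0, "sp_b": 1}),
        DungSample("s3", "a2", pd.Timestamp("2018-06-10"), 100.0,
                   {"sp_a": 26}),
        DungSample("s4", "a2", pd.Timestamp("2018-07-10"), 200.0,
                   {"sp_b": 4}),
    ]
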