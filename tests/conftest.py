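import pathlib

import matplotlib
import numpy as np
import pandas as pd
import pytest

matplotlib.use("Agg")

from stsa.io import Dataset
from stsa.synth import GeneratorConfig, generate_dataset

DATA = pathlib.Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def fixture_paths():
    return DATA / "trials_small.csv", DATA / "trajectories_small.csv"


@pytest.fixture(scope="session")
def small_dataset():
    """Deterministic small synthetic dataset (4 participants, both devices)."""
    cfg = GeneratorConfig(seed=123, n_participants=4, trials_per_condition=12)
    ds, manifest = generate_dataset(cfg)
    return ds, manifest


def make_dataset(trials_rows, traj_rows=()):
    """Hand-built dataset from row dicts (test helper)."""
    trials = pd.DataFrame(trials_rows)
    traj = (pd.DataFrame(traj_rows) if len(traj_rows)
            else pd.DataFrame(columns=["trial_id", "t_ms", "x_m"]))
    return Dataset(trials, traj)


def straight_trajectory(delay_ms, speed_m_s, end_x_m, rate_hz=90.0,
                        t0=0.0):
    """Noiseless hold-then-move trajectory, for analytic checks."""
    dt = 1000.0 / rate_hz
    side = np.sign(end_x_m)
    t, x = [t0], [0.0]
    while True:
        tn = t[-1] + dt
        xn = x[-1]
        if tn > delay_ms:
            xn = x[-1] + side * speed_m_s * dt / 1000.0
            if abs(xn) >= abs(end_x_m):
                xn = end_x_m
        t.append(tn)
        x.append(xn)
        if xn == end_x_m:
            return np.array(t), np.array(x)
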