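"""Reading, writing and validating trial and trajectory tables.

Data are exchanged in two long-format CSV tables:

``trial_table``
    one row per trial with columns ``trial_id, participant, device,
    n_back, trial_type, rt_ms, accuracy``.  ``device`` is ``classical``
    (key-press) or ``vr`` (tracked movement); ``trial_type`` is ``match``
    or ``nonmatch``; ``rt_ms`` is the response completion time in
    milliseconds and ``accuracy`` is 1/0, both left blank for unfinished
    trials (the response never reached a box).

``trajectory_table``
    one row per tracked sample with columns ``trial_id, t_ms, x_m``.
    ``t_ms`` counts milliseconds from stimulus onset (the first sample
    may sit at 0); ``x_m`` is the signed position on the axis joining
    the two response boxes, **positive toward the Match box** for every
    trial.  Counterbalancing of physical box sides is undone at load
    time so that correctness can always be derived from sign x
    trial type downstream.

Both files are UTF-8 CSV with a mandatory header and ``.`` decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "SchemaError",
    "ValidationError",
    "read_trials",
    "write_trials",
    "signed_position",
    "TRIAL_COLUMNS",
    "TRAJECTORY_COLUMNS",
]

TRIAL_COLUMNS = [
    "trial_id",
    "participant",
    "device",
    "n_back",
    "trial_type",
    "rt_ms",
    "accuracy",
]
TRAJECTORY_COLUMNS = ["trial_id", "t_ms", "x_m"]

DEVICES = frozenset({"classical", "vr"})
TRIAL_TYPES = frozenset({"match", "nonmatch"})
N_BACK_LEVELS = frozenset({1, 2, 3})


class SchemaError(ValueError):
    """A table does not conform to the documented column schema."""


class ValidationError(ValueError):
    """A table is schematically fine but semantically inconsistent."""


def signed_position(dist_to_match, dist_to_nonmatch):
    """Signed box-axis position from the two box distances.

    Parameters
    ----------
    dist_to_match, dist_to_nonmatch : float or array-like
        Distances A and B (meters, >= 0) from the carried stimulus to
        the Match and non-Match box respectively.

    Returns
    -------
    float or ndarray
        ``(B - A) / 2`` -- zero when equidistant, positive toward the
        Match box.  Halving makes ``|x|`` at a box center equal half
        the box separation, so a 0.4 m separation puts the boxes at
        +/-0.2 m.
    """
    a = np.asarray(dist_to_match, dtype=float)
    b = np.asarray(dist_to_nonmatch, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("box distances must be non-negative")
    x = (b - a) / 2.0
    if np.ndim(dist_to_match) == 0 and np.ndim(dist_to_nonmatch) == 0:
        return float(x)
    return x


@dataclass
class Dataset:
    """A collection of trials plus their (optional) trajectories.

    Attributes
    ----------
    trials : pandas.DataFrame
        One row per trial, columns :data:`TRIAL_COLUMNS`.
    trajectories : pandas.DataFrame
        Long-format samples, columns :data:`TRAJECTORY_COLUMNS`,
        time-sorted within each trial.  May be empty for datasets of
        classical trials only.
    metadata : dict
        Free-form provenance (source file, generator config, seed).
    """

    trials: pd.DataFrame
    trajectories: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    )
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.trials = _coerce_trials(self.trials)
        self.trajectories = _coerce_trajectories(self.trajectories)

    # -- accessors -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.trials)

    def trajectory(self, trial_id) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(t_ms, x_m)`` arrays for one trial."""
        g = self.trajectories[self.trajectories["trial_id"] == trial_id]
        if g.empty:
            raise KeyError(f"trial {trial_id!r} has no trajectory")
        return g["t_ms"].to_numpy(float), g["x_m"].to_numpy(float)

    def iter_trajectories(self) -> Iterable[tuple[pd.Series, np.ndarray, np.ndarray]]:
        """Yield ``(trial_row, t_ms, x_m)`` for every trial with samples."""
        by_id = dict(iter(self.trajectories.groupby("trial_id", sort=False)))
        for _, row in self.trials.iterrows():
            g = by_id.get(row["trial_id"])
            if g is not None:
                yield row, g["t_ms"].to_numpy(float), g["x_m"].to_numpy(float)

    # -- validation ----------------------------------------------------
    def validate(self) -> "Dataset":
        """Check all dataset invariants; raise on violation, return self."""
        t = self.trials
        if t["trial_id"].duplicated().any():
            dup = t.loc[t["trial_id"].duplicated(), "trial_id"].iloc[0]
            raise SchemaError(f"duplicated trial_id {dup!r}")
        bad_dev = set(t["device"]) - DEVICES
        if bad_dev:
            raise ValidationError(f"unknown device value(s) {sorted(bad_dev)}")
        bad_tt = set(t["trial_type"]) - TRIAL_TYPES
        if bad_tt:
            raise ValidationError(f"unknown trial_type value(s) {sorted(bad_tt)}")
        bad_n = set(t["n_back"].astype(int)) - N_BACK_LEVELS
        if bad_n:
            raise ValidationError(f"n_back must be in {{1,2,3}}, got {sorted(bad_n)}")
        rt = t["rt_ms"]
        if (rt.dropna() <= 0).any():
            raise ValidationError("rt_ms must be > 0 where present")
        # finished trials need both RT and accuracy; unfinished need neither
        if (rt.isna() != t["accuracy"].isna()).any():
            bad = t.loc[rt.isna() != t["accuracy"].isna(), "trial_id"].iloc[0]
            raise ValidationError(
                f"trial {bad!r}: rt_ms and accuracy must be jointly present or absent"
            )
        known = set(t["trial_id"])
        orphan = set(self.trajectories["trial_id"]) - known
        if orphan:
            raise ValidationError(f"trajectory rows for unknown trial(s) {sorted(orphan)[:3]}")
        for tid, g in self.trajectories.groupby("trial_id", sort=False):
            dt = np.diff(g["t_ms"].to_numpy(float))
            if len(dt) and dt.min() <= 0:
                raise ValidationError(f"trial {tid!r}: timestamps not strictly increasing")
        return self


def _coerce_trials(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial table missing column(s) {missing}")
    df = df.loc[:, TRIAL_COLUMNS].copy()
    df["n_back"] = df["n_back"].astype(int)
    df["rt_ms"] = pd.to_numeric(df["rt_ms"], errors="coerce")
    df["accuracy"] = pd.to_numeric(df["accuracy"], errors="coerce")
    df["device"] = df["device"].astype(str)
    df["trial_type"] = df["trial_type"].astype(str)
    return df.reset_index(drop=True)


def _coerce_trajectories(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trajectory table missing column(s) {missing}")
    df = df.loc[:, TRAJECTORY_COLUMNS].copy()
    df["t_ms"] = pd.to_numeric(df["t_ms"])
    df["x_m"] = pd.to_numeric(df["x_m"])
    # time-sort within trial while preserving trial order of first appearance
    df = df.sort_values(["trial_id", "t_ms"], kind="stable").reset_index(drop=True)
    return df


def read_trials(trials_path, trajectories_path=None) -> Dataset:
    """Load a trial table (and optionally a trajectory table) from CSV.

    Trajectory rows are grouped by ``trial_id`` and time-sorted, so a
    shuffled file loads to the same dataset as a sorted one.  Raises
    :class:`SchemaError` for missing columns or duplicated trial ids and
    :class:`ValidationError` for non-monotone (tied) timestamps.
    """
    trials_path = Path(trials_path)
    trials = pd.read_csv(trials_path)
    if trajectories_path is not None:
        trajectories = pd.read_csv(trajectories_path)
    else:
        trajectories = pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    ds = Dataset(trials, trajectories, metadata={"source": str(trials_path)})
    return ds.validate()


def write_trials(dataset: Dataset, trials_path, trajectories_path=None) -> None:
    """Write a dataset back to CSV; inverse of :func:`read_trials`.

    An empty dataset produces a header-only file.  The trajectory table
    is written only when a path is given; for classical-only datasets it
    is empty either way.
    """
    dataset.validate()
    Path(trials_path).parent.mkdir(parents=True, exist_ok=True)
    dataset.trials.to_csv(trials_path, index=False)
    if trajectories_path is not None:
        dataset.trajectories.to_csv(trajectories_path, index=False)
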