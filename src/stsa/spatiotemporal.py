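"""Spatiotemporal survival analysis (StSA) of movement trajectories.

The pipeline has four stages:

* **Stage 0** -- averaged trajectories per condition
  (:func:`average_trajectories`), a coarse overview.
* **Stage 1** -- single-trial series; no computation beyond plotting,
  the raw dataset is the artifact.
* **Stage 2** -- high-resolution occupancy heat maps
  (:func:`occupancy`): how many trajectories visit each spatiotemporal
  cell, usually viewed on a log scale (:func:`log_view`).
* **Stage 3** -- survival analysis over space *and* time: each trial is
  reduced to first-crossing events of 20 nested spatial thresholds
  (5% of the total distance each, :func:`extract_crossings`); per
  threshold row the events define a discrete-time hazard ``H`` and a
  conditional accuracy ``CA`` over time bins (:func:`stsa_maps`).

A crossing event's *direction* (sign of x at the crossing sample)
scores segment-level accuracy: moving toward the Match box is correct
on Match trials and incorrect on non-Match trials, regardless of how
the trial ultimately ends.  This lets H and CA describe ongoing,
possibly self-correcting movement, not just completed responses.

No trimming is ever applied at this level; trajectories past the
display window are truncated from displays only and kept in every
risk set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import Dataset
from .survival import TemporalGrid, bin_index

__all__ = [
    "StsaGrid",
    "OccupancyGrid",
    "StsaMaps",
    "ScalingError",
    "average_trajectories",
    "occupancy",
    "log_view",
    "extract_crossings",
    "crossing_events",
    "trajectory_end_bins",
    "stsa_maps",
    "stsa_hazard",
    "stsa_ca",
    "scale_maps",
    "early_window_counts",
]


class ScalingError(ValueError):
    """Raised when hazard maps cannot be rescaled (all-zero input)."""


@dataclass(frozen=True)
class StsaGrid:
    """Stage-3 grid: nested spatial thresholds x time bins.

    The trajectory's reach is divided into ``n_spatial_bins`` thresholds
    spaced ``spatial_bin_width_m`` apart; with the defaults (20 bins of
    0.01 m) each threshold adds 5% of the 0.20 m total distance and the
    grid has 20 x 70 = 1400 display cells.
    """

    spatial_bin_width_m: float = 0.01
    n_spatial_bins: int = 20
    temporal: TemporalGrid = field(default_factory=TemporalGrid)

    def __post_init__(self) -> None:
        if self.spatial_bin_width_m <= 0 or self.n_spatial_bins < 1:
            raise ValueError("invalid spatial grid")

    @property
    def total_distance_m(self) -> float:
        return self.n_spatial_bins * self.spatial_bin_width_m

    @property
    def thresholds_m(self) -> np.ndarray:
        """Strictly increasing threshold values ``k * total / n``, k=1..n."""
        return (np.arange(1, self.n_spatial_bins + 1)
                * self.total_distance_m / self.n_spatial_bins)

    @property
    def n_cells(self) -> int:
        return self.n_spatial_bins * self.temporal.n_display_bins


@dataclass
class OccupancyGrid:
    """Stage-2 grid and counts.

    Cells are right-closed in both axes.  Defaults give 101 spatial bins
    of 0.008 m spanning (-0.404, 0.404] m and 701 temporal bins of
    10 ms spanning (0, 7010] ms -- 70,801 cells.  ``counts`` has shape
    ``(n_spatial, n_temporal)``; ``n_dropped_samples`` tallies samples
    falling outside either range.
    """

    x_min_m: float = -0.404
    x_max_m: float = 0.404
    n_spatial: int = 101
    t_bin_ms: float = 10.0
    n_temporal: int = 701
    counts: np.ndarray | None = None
    transform: str = "raw"
    counting: str = "per_trajectory"
    n_dropped_samples: int = 0

    @property
    def x_bin_width_m(self) -> float:
        return (self.x_max_m - self.x_min_m) / self.n_spatial

    @property
    def n_cells(self) -> int:
        return self.n_spatial * self.n_temporal

    @property
    def x_edges(self) -> np.ndarray:
        return np.linspace(self.x_min_m, self.x_max_m, self.n_spatial + 1)

    @property
    def t_edges(self) -> np.ndarray:
        return np.arange(self.n_temporal + 1) * self.t_bin_ms


@dataclass
class StsaMaps:
    """Stage-3 per-cell counts and estimates for one condition.

    Arrays have shape ``(n_spatial_bins, n_time_bins)`` where the time
    axis runs to the last observed bin (>= the display window).  ``H``
    is events / at-risk (0 where nobody is at risk); ``CA`` is the mean
    crossing correctness, NaN where no events occurred.  ``scale_`` is
    set by :func:`scale_maps`.
    """

    grid: StsaGrid
    n_trials: int
    n_events: np.ndarray
    n_at_risk: np.ndarray
    H: np.ndarray
    CA: np.ndarray
    label: tuple = field(default_factory=tuple)
    scale_: float | None = None

    @property
    def n_time_bins(self) -> int:
        return self.n_events.shape[1]

    def display(self, arr_name: str = "H") -> np.ndarray:
        """Array truncated to the display window (right-censored view)."""
        arr = getattr(self, arr_name)
        return arr[:, : self.grid.temporal.n_display_bins]


# ---------------------------------------------------------------------
# Stage 0
# ---------------------------------------------------------------------

def average_trajectories(dataset: Dataset, step_ms: float | None = None,
                         trial_ids=None) -> pd.DataFrame:
    """Mean trajectory over trials, with the number contributing.

    At each grid time the mean runs over the trials whose recording
    extends at least that far; there is no padding or extrapolation, so
    toward the right edge fewer and fewer responses contribute (the
    ``n`` column makes that visible).  ``step_ms`` defaults to the
    median sampling period of the data.
    """
    trajs = []
    for row, t, x in dataset.iter_trajectories():
        if trial_ids is None or row["trial_id"] in set(trial_ids):
            trajs.append((t, x))
    if not trajs:
        raise ValueError("no trajectories to average")
    if step_ms is None:
        periods = [np.median(np.diff(t)) for t, _ in trajs if len(t) > 1]
        step_ms = float(np.median(periods)) if periods else 1000.0 / 90.0
    t_max = max(t[-1] for t, _ in trajs)
    grid_t = np.arange(0.0, t_max + step_ms / 2, step_ms)
    sums = np.zeros_like(grid_t)
    n = np.zeros_like(grid_t, dtype=int)
    for t, x in trajs:
        m = grid_t <= t[-1]
        sums[m] += np.interp(grid_t[m], t, x)
        n[m] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, sums / np.maximum(n, 1), np.nan)
    return pd.DataFrame({"t_ms": grid_t, "x_mean_m": mean, "n": n})


# ---------------------------------------------------------------------
# Stage 2
# ---------------------------------------------------------------------

def occupancy(dataset: Dataset, grid: OccupancyGrid | None = None,
              counting: str = "per_trajectory") -> OccupancyGrid:
    """Count trajectory visits per spatiotemporal cell.

    ``per_trajectory`` (default): a cell increments at most once per
    trial -- the map shows how many *trajectories* visit each cell.
    ``per_sample``: every sample increments its cell (diagnostic mode;
    the grand total then equals the number of in-range samples).
    Samples outside the spatial or temporal range are dropped and
    tallied in ``n_dropped_samples``.
    """
    if counting not in ("per_trajectory", "per_sample"):
        raise ValueError(f"unknown counting mode {counting!r}")
    grid = grid or OccupancyGrid()
    counts = np.zeros((grid.n_spatial, grid.n_temporal), dtype=int)
    dropped = 0
    for _, t, x in dataset.iter_trajectories():
        xi = np.digitize(x, grid.x_edges, right=True)
        ti = np.digitize(t, grid.t_edges, right=True)
        ok = (xi >= 1) & (xi <= grid.n_spatial) & (ti >= 1) & (ti <= grid.n_temporal)
        dropped += int((~ok).sum())
        cells = (xi[ok] - 1) * grid.n_temporal + (ti[ok] - 1)
        if counting == "per_trajectory":
            cells = np.unique(cells)
        np.add.at(counts.reshape(-1), cells, 1)
    return replace(grid, counts=counts, counting=counting,
                   n_dropped_samples=dropped, transform="raw")


def log_view(counts) -> np.ndarray:
    """``log10(count + 1)`` view of occupancy counts (0 maps to 0)."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    return np.log10(c + 1.0)


# ---------------------------------------------------------------------
# Stage 3
# ---------------------------------------------------------------------

def extract_crossings(t_ms, x_m, trial_type: str,
                      grid: StsaGrid | None = None) -> pd.DataFrame:
    """First-crossing events of every spatial threshold for one trial.

    For each threshold the event is the first sample with
    ``|x| >= threshold``; its direction (sign of x there) determines
    correctness: ``+`` (toward Match) is correct on Match trials, ``-``
    on non-Match trials.  Thresholds never reached yield no event.
    Returns a frame with one row per crossed threshold: columns
    ``threshold_index`` (1-based), ``threshold_m``, ``t_ms``,
    ``time_bin``, ``direction`` (+1/-1), ``correct``.

    Times need not be non-decreasing in the threshold index -- a dip
    toward the wrong box can cross small thresholds long before large
    ones are reached on the way back.
    """
    grid = grid or StsaGrid()
    t = np.asarray(t_ms, dtype=float)
    x = np.asarray(x_m, dtype=float)
    if t.size == 0:
        raise ValueError("empty trajectory")
    if t.size > 1 and np.diff(t).min() <= 0:
        raise ValueError("timestamps not strictly increasing")
    if trial_type not in ("match", "nonmatch"):
        raise ValueError(f"unknown trial_type {trial_type!r}")

    running_max = np.maximum.accumulate(np.abs(x))
    thresholds = grid.thresholds_m
    # first index where the running max reaches each threshold; the tiny
    # slack keeps exact-tie crossings (|x| == threshold) from being lost
    # to floating-point representation
    idx = np.searchsorted(running_max, thresholds - 1e-12, side="left")
    crossed = idx < t.size
    idx = idx[crossed]
    k = np.arange(1, grid.n_spatial_bins + 1)[crossed]
    direction = np.sign(x[idx]).astype(int)
    correct = (direction > 0) == (trial_type == "match")
    tev = t[idx]
    time_bin = np.where(tev > 0,
                        np.ceil(np.maximum(tev, 1e-9) / grid.temporal.bin_width_ms),
                        1).astype(int)
    return pd.DataFrame({
        "threshold_index": k,
        "threshold_m": thresholds[crossed],
        "t_ms": tev,
        "time_bin": time_bin,
        "direction": direction,
        "correct": correct,
    })


def crossing_events(dataset: Dataset, grid: StsaGrid | None = None) -> pd.DataFrame:
    """Crossing events for every trial with a trajectory, labelled.

    Concatenates :func:`extract_crossings` over the dataset, attaching
    ``trial_id, participant, device, n_back, trial_type`` to each event.
    """
    grid = grid or StsaGrid()
    frames = []
    for row, t, x in dataset.iter_trajectories():
        ev = extract_crossings(t, x, row["trial_type"], grid)
        if ev.empty:
            continue
        for col in ("trial_type", "n_back", "device", "participant", "trial_id"):
            ev.insert(0, col, row[col])
        frames.append(ev)
    cols = ["trial_id", "participant", "device", "n_back", "trial_type",
            "threshold_index", "threshold_m", "t_ms", "time_bin",
            "direction", "correct"]
    if not frames:
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)[cols]


def trajectory_end_bins(dataset: Dataset, grid: StsaGrid | None = None) -> pd.Series:
    """Time bin of each trajectory's last sample, indexed by trial id.

    Defines when a never-crossing trial leaves the risk sets: a trial
    contributes to a threshold's risk set until its recording ends.
    """
    grid = grid or StsaGrid()
    ids, ends = [], []
    for row, t, x in dataset.iter_trajectories():
        ids.append(row["trial_id"])
        last = t[-1]
        ends.append(bin_index(last, grid.temporal) if last > 0 else 1)
    return pd.Series(ends, index=pd.Index(ids, name="trial_id"), name="end_bin")


def stsa_maps(events: pd.DataFrame, end_bins: pd.Series,
              grid: StsaGrid | None = None, label: tuple = ()) -> StsaMaps:
    """Spatiotemporal hazard and conditional accuracy from crossing events.

    Each spatial row ``k`` is an independent discrete-time hazard over
    the first crossings of threshold ``k``: at bin ``t`` the risk set
    holds every trial whose first crossing of ``k`` happens in bin
    ``>= t``, plus trials that never cross ``k`` whose recording is
    still running (``end_bin >= t``).  ``H(k,t)`` is events / at-risk;
    ``CA(k,t)`` is the mean correctness of the events in the cell, NaN
    where there are none.

    Parameters
    ----------
    events : DataFrame
        Output of :func:`crossing_events` (or a condition slice of it).
    end_bins : Series
        Last-sample bin for **all** trials of the condition, including
        trials without any event (from :func:`trajectory_end_bins`).
    """
    grid = grid or StsaGrid()
    n_trials = len(end_bins)
    if n_trials == 0:
        raise ValueError("no trials in risk set")
    max_ev = int(events["time_bin"].max()) if len(events) else 0
    n_bins = max(grid.temporal.n_display_bins, int(end_bins.max()), max_ev)
    K = grid.n_spatial_bins

    n_events = np.zeros((K, n_bins), dtype=int)
    n_corr = np.zeros((K, n_bins))
    n_at_risk = np.zeros((K, n_bins), dtype=int)

    ev_by_k = {k: g for k, g in events.groupby("threshold_index")} if len(events) else {}
    end = end_bins.to_numpy()
    for k in range(1, K + 1):
        g = ev_by_k.get(k)
        if g is not None:
            tb = g["time_bin"].to_numpy() - 1
            np.add.at(n_events[k - 1], tb, 1)
            np.add.at(n_corr[k - 1], tb, g["correct"].to_numpy(float))
            crossed_ids = set(g["trial_id"]) if "trial_id" in g else None
        else:
            crossed_ids = set()
        # risk set: crossers until their event bin, never-crossers until
        # their last sample bin
        if g is not None and "trial_id" in g:
            uncrossed = ~end_bins.index.isin(g["trial_id"])
        elif g is not None:
            # unlabeled single-trial input: all trials crossed
            uncrossed = np.zeros(n_trials, dtype=bool)
        else:
            uncrossed = np.ones(n_trials, dtype=bool)
        exit_bins = np.concatenate([
            g["time_bin"].to_numpy() if g is not None else np.empty(0, dtype=int),
            end[uncrossed],
        ])
        # at_risk(t) = #{exit_bin >= t}
        cnt = np.bincount(exit_bins, minlength=n_bins + 1)[1:]
        n_at_risk[k - 1] = cnt[::-1].cumsum()[::-1]

    with np.errstate(invalid="ignore", divide="ignore"):
        H = np.where(n_at_risk > 0, n_events / np.maximum(n_at_risk, 1), 0.0)
        CA = np.where(n_events > 0, n_corr / np.maximum(n_events, 1), np.nan)
    return StsaMaps(grid, n_trials, n_events, n_at_risk, H, CA, label=tuple(label))


def stsa_hazard(events: pd.DataFrame, end_bins: pd.Series,
                grid: StsaGrid | None = None) -> np.ndarray:
    """Hazard map only; see :func:`stsa_maps`."""
    return stsa_maps(events, end_bins, grid).H


def stsa_ca(events: pd.DataFrame, end_bins: pd.Series,
            grid: StsaGrid | None = None) -> np.ndarray:
    """Conditional-accuracy map only; see :func:`stsa_maps`."""
    return stsa_maps(events, end_bins, grid).CA


def scale_maps(maps_by_condition: dict) -> dict:
    """Scale hazard maps by the single maximum across all conditions.

    Returns new :class:`StsaMaps` objects whose ``H`` is divided by the
    global maximum (which thereby becomes exactly 1 somewhere in the
    set); relative order of any two cells, within or across maps, is
    preserved.  ``scale_`` records the divisor.  Raises
    :class:`ScalingError` when every map is all-zero.
    """
    if not maps_by_condition:
        raise ScalingError("no maps to scale")
    global_max = max(float(m.H.max()) for m in maps_by_condition.values())
    if global_max <= 0:
        raise ScalingError("all hazard maps are zero; nothing to scale")
    out = {}
    for key, m in maps_by_condition.items():
        out[key] = StsaMaps(m.grid, m.n_trials, m.n_events, m.n_at_risk,
                            m.H / global_max, m.CA, label=m.label,
                            scale_=global_max)
    return out


def early_window_counts(events: pd.DataFrame, window_ms=(0.0, 500.0),
                        by=("participant", "n_back", "trial_type")):
    """Distinct trials with a crossing event in an early time window.

    Counts, per grouping cell, the number of *unique* trials having at
    least one crossing event with time in ``(window_ms[0], window_ms[1]]``
    (right-closed).  Returns ``(counts, summary)`` where ``summary``
    reports n (total trials), mean, SD, min and max of the per-cell
    counts -- the robustness table for early-movement evidence.
    """
    by = list(by)
    lo, hi = window_ms
    sel = events[(events["t_ms"] > lo) & (events["t_ms"] <= hi)]
    counts = (sel.groupby(by, sort=True)["trial_id"].nunique()
              .rename("n_trials").reset_index())
    vals = counts["n_trials"].to_numpy(float)
    summary = pd.DataFrame({
        "n_trials_total": [int(vals.sum()) if len(vals) else 0],
        "n_cells": [len(vals)],
        "mean": [vals.mean() if len(vals) else np.nan],
        "sd": [vals.std(ddof=1) if len(vals) > 1 else np.nan],
        "min": [vals.min() if len(vals) else np.nan],
        "max": [vals.max() if len(vals) else np.nan],
    })
    return counts, summary
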