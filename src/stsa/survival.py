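"""Discrete-time survival analysis of completed responses.

Response completion times are assigned to left-open, right-closed time
bins ``((k-1)w, kw]`` (default width 100 ms).  Over those bins we
estimate three sample-based functions:

hazard ``h(t) = P(T = t | T >= t)``
    the conditional probability that a response completes in bin *t*
    given it has not completed before,

survivor ``S(t) = P(T > t)``
    the fraction of trials still without a response at the end of bin
    *t* (``S(0) = 1``),

conditional accuracy ``ca(t) = P(correct | T = t)``
    the accuracy of the responses completing in bin *t*, undefined in
    bins with no events.

There is no Kaplan-Meier censoring machinery: the analysis keeps every
completed trial, and the 70-bin display window together with the 5%
mask (:func:`mask_from`) are presentation concerns only -- estimation
always runs over the full tail.  Curves are by default pooled over
participants within a condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Dataset

__all__ = [
    "TemporalGrid",
    "SurvivalCurves",
    "bin_index",
    "estimate_survival",
    "median_rt",
    "mask_from",
    "survival_by",
    "curves_to_frame",
]


@dataclass(frozen=True)
class TemporalGrid:
    """Uniform time binning: bin ``k`` covers ``((k-1)w, kw]`` ms."""

    bin_width_ms: float = 100.0
    n_display_bins: int = 70

    def __post_init__(self) -> None:
        if self.bin_width_ms <= 0:
            raise ValueError("bin_width_ms must be > 0")
        if self.n_display_bins < 1:
            raise ValueError("n_display_bins must be >= 1")

    @property
    def display_span_ms(self) -> float:
        return self.bin_width_ms * self.n_display_bins


def bin_index(t_ms, grid: TemporalGrid | None = None):
    """Ordinal of the bin containing time ``t_ms`` (1-based).

    Bins are right-closed, so 3650 ms and 3700 ms both land in bin 37 of
    the default 100 ms grid.  Times beyond the display window return
    their true ordinal; truncation is a display concern.
    """
    grid = grid or TemporalGrid()
    t = np.asarray(t_ms, dtype=float)
    if np.any(t <= 0):
        raise ValueError("bin_index requires t > 0")
    k = np.ceil(t / grid.bin_width_ms).astype(int)
    return int(k) if np.ndim(t_ms) == 0 else k


@dataclass
class SurvivalCurves:
    """Per-bin counts and estimates for one condition.

    Arrays run over bins ``1..n_bins`` where ``n_bins`` is the bin of
    the slowest response (possibly beyond the display window); slicing
    to the display window is left to presentation code.  ``ca`` holds
    NaN exactly where ``n_events == 0``.
    """

    grid: TemporalGrid
    n_trials: int
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n_correct: np.ndarray
    h: np.ndarray
    S: np.ndarray
    ca: np.ndarray
    label: tuple = field(default_factory=tuple)

    @property
    def n_bins(self) -> int:
        return len(self.n_events)

    @property
    def bins(self) -> np.ndarray:
        return np.arange(1, self.n_bins + 1)

    @property
    def bin_upper_edges_ms(self) -> np.ndarray:
        return self.bins * self.grid.bin_width_ms


def estimate_survival(rt_ms, correct, grid: TemporalGrid | None = None,
                      label: tuple = ()) -> SurvivalCurves:
    """Estimate h, S and ca from completed response times.

    Parameters
    ----------
    rt_ms : array-like of float
        Completion times in ms, all > 0 and finite (completed trials of
        one condition).
    correct : array-like of bool/int
        Final accuracy per trial, aligned with ``rt_ms``.
    grid : TemporalGrid, optional
        Time binning, default 100 ms bins.
    """
    grid = grid or TemporalGrid()
    rt = np.asarray(rt_ms, dtype=float)
    acc = np.asarray(correct, dtype=float)
    if rt.size == 0:
        raise ValueError("estimate_survival needs at least one trial")
    if rt.shape != acc.shape:
        raise ValueError("rt_ms and correct must be aligned")
    if np.any(~np.isfinite(rt)) or np.any(~np.isfinite(acc)):
        raise ValueError("completed trials must have finite rt_ms and accuracy")

    bins = bin_index(rt, grid)
    bins = np.atleast_1d(bins)
    n = rt.size
    n_bins = int(bins.max())
    n_events = np.bincount(bins, minlength=n_bins + 1)[1:].astype(int)
    n_correct = np.bincount(bins, weights=acc, minlength=n_bins + 1)[1:]
    # at-risk in bin t: trials whose response falls in bin >= t
    n_at_risk = n - np.concatenate(([0], np.cumsum(n_events)[:-1]))
    h = n_events / n_at_risk
    S = 1.0 - np.cumsum(n_events) / n
    with np.errstate(invalid="ignore"):
        ca = np.where(n_events > 0, n_correct / np.maximum(n_events, 1), np.nan)
    return SurvivalCurves(grid, n, n_at_risk.astype(int), n_events,
                          n_correct, h, S, ca, label=tuple(label))


def median_rt(curves: SurvivalCurves):
    """Median completion time from ``S(t) = 0.50`` by linear interpolation.

    Interpolates S against the bin *upper edges* (with ``S = 1`` at
    ``t = 0``); an exact hit returns that edge.  Returns ``None`` --
    distinctly from raising -- when S never reaches 0.5 (heavy
    censoring), as no median is identified.
    """
    w = curves.grid.bin_width_ms
    s_prev, t_prev = 1.0, 0.0
    for k in range(curves.n_bins):
        s_k = curves.S[k]
        t_k = (k + 1) * w
        if s_k == 0.5:
            return float(t_k)
        if s_k < 0.5:
            # solve s_prev + (s_k - s_prev) * f = 0.5 on [t_prev, t_k]
            f = (s_prev - 0.5) / (s_prev - s_k)
            return float(t_prev + f * w)
        s_prev, t_prev = s_k, t_k
    return None


def mask_from(curves: SurvivalCurves, threshold: float = 0.05):
    """First bin ordinal with ``S(t) < threshold``, or ``None``.

    Downstream plots grey bins at and beyond this ordinal (the sparse
    right tail holding less than ``threshold`` of the trials); the
    estimates themselves are never altered.
    """
    below = np.nonzero(curves.S < threshold)[0]
    if below.size == 0:
        return None
    return int(below[0]) + 1


def survival_by(dataset: Dataset, by=("device", "n_back", "trial_type"),
                grid: TemporalGrid | None = None) -> dict:
    """Pooled survival curves per condition cell.

    Only completed trials (``rt_ms`` and ``accuracy`` present) enter;
    unfinished trials carry no completion time and are excluded here
    (they still participate in the trajectory-level analyses).
    Returns ``{condition tuple: SurvivalCurves}``.
    """
    grid = grid or TemporalGrid()
    by = list(by)
    t = dataset.trials
    done = t[t["rt_ms"].notna() & t["accuracy"].notna()]
    out = {}
    for key, g in done.groupby(by, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        out[key] = estimate_survival(g["rt_ms"].to_numpy(),
                                     g["accuracy"].to_numpy(),
                                     grid, label=key)
    return out


def curves_to_frame(curves_by_condition: dict, by=("device", "n_back", "trial_type"),
                    mask_threshold: float = 0.05) -> pd.DataFrame:
    """Tidy per-bin table for a set of conditions (CSV-friendly).

    One row per condition x bin with counts and estimates, plus the
    per-condition median RT and mask ordinal repeated on each row.
    """
    frames = []
    for key, c in curves_by_condition.items():
        df = pd.DataFrame({
            "bin": c.bins,
            "bin_upper_ms": c.bin_upper_edges_ms,
            "n_at_risk": c.n_at_risk,
            "n_events": c.n_events,
            "h": c.h,
            "S": c.S,
            "ca": c.ca,
        })
        for name, val in zip(by, key):
            df.insert(0, name, val)
        med = median_rt(c)
        mask = mask_from(c, mask_threshold)
        df["median_rt_ms"] = np.nan if med is None else med
        df["mask_from_bin"] = np.nan if mask is None else mask
        frames.append(df)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def geometric_se(p: float, n_at_risk) -> np.ndarray:
    """Binomial standard error of a hazard estimate at true rate ``p``."""
    n = np.asarray(n_at_risk, dtype=float)
    return np.sqrt(p * (1 - p) / np.maximum(n, 1))
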