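"""Classical inferential chain: trimming, diagnostics, ANOVA, post-hocs.

The centrepiece is :func:`rm_anova`, a general *balanced* repeated-
measures / split-plot ANOVA with any number of within-participant
factors (and optionally between-participant factors).  Sums of squares
come from the classical inclusion-exclusion decomposition with the
participant as a random factor: each within effect is tested against
its interaction with participants (within groups), between effects
against participants-within-groups.  Reported per effect: F, degrees
of freedom, p, partial eta-squared ``SS_effect / (SS_effect +
SS_error)``, and for within effects with >= 2 numerator df the
Greenhouse-Geisser epsilon with the sphericity-corrected p alongside.

Outlier trimming follows the conventional two-stage recipe for
reaction times -- 1.5-IQR fences per condition (quartiles by linear
interpolation, i.e. quantile type 7), then mean +/- 2 SD -- with a
removal report at each stage expressed relative to the previous
stage's count.  Trimming is used for the mean-based ANOVAs only; the
survival-based analyses always run on untrimmed data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TrimResult",
    "DesignError",
    "iqr_trim",
    "sd_trim",
    "trim_pipeline",
    "variance_diagnostics",
    "rm_anova",
    "posthoc_pairwise",
    "windowed_ca_table",
    "windowed_ca_anova",
]


class DesignError(ValueError):
    """The data do not form the balanced design an operation requires."""


# ---------------------------------------------------------------------
# Trimming
# ---------------------------------------------------------------------

@dataclass
class TrimResult:
    values: np.ndarray
    kept: np.ndarray          # boolean mask over the input
    lower: float
    upper: float

    @property
    def n_input(self) -> int:
        return self.kept.size

    @property
    def n_removed(self) -> int:
        return int((~self.kept).sum())

    @property
    def pct_removed(self) -> float:
        """Removed / input count of *this* stage, in percent."""
        return 100.0 * self.n_removed / self.n_input


def iqr_trim(values, k: float = 1.5) -> TrimResult:
    """Quartile outlier rejection: keep values inside the 1.5-IQR fences.

    Quartiles use linear interpolation (type 7, numpy's default), so
    for ``{1,2,3,4,100}`` Q1=2 and Q3=4, giving fences [-1, 7] and
    dropping the 100.  Requires at least 4 values.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("iqr_trim needs at least 4 values")
    q1, q3 = np.quantile(v, [0.25, 0.75])   # linear interpolation = type 7
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    kept = (v >= lo) & (v <= hi)
    return TrimResult(v[kept], kept, float(lo), float(hi))


def sd_trim(values, n_sd: float = 2.0, one_sided: bool = False) -> TrimResult:
    """Keep values within mean +/- ``n_sd`` sample standard deviations.

    Mean and SD (ddof=1) are taken from the input values.  With
    ``one_sided=True`` only the upper bound applies (the alternative
    reading of "mean plus two times standard deviation").
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("sd_trim needs at least 2 values")
    m, s = v.mean(), v.std(ddof=1)
    lo = -np.inf if one_sided else m - n_sd * s
    hi = m + n_sd * s
    kept = (v >= lo) & (v <= hi)
    return TrimResult(v[kept], kept, float(lo), float(hi))


def trim_pipeline(trials: pd.DataFrame, value: str = "rt_ms",
                  by=("device", "n_back", "trial_type"),
                  drop_errors: bool = False, one_sided_sd: bool = False):
    """Per-condition IQR trim, then SD trim, then optional error removal.

    Replicates the conventional accounting for mean-RT analyses: each
    stage's removal percentage is reported relative to the count
    *entering* that stage.  Condition cells too small to trim (< 4
    values for the IQR stage, < 2 for the SD stage) pass through
    untrimmed.  Returns ``(kept_trials, report)`` where ``report`` is a
    DataFrame with one row per stage (stage name, n_in, n_removed,
    pct_removed).
    """
    by = list(by)
    df = trials[trials[value].notna()].copy()
    report = []

    def _stage(frame, name, trimmer):
        keep_idx = []
        for _, g in frame.groupby(by, sort=False):
            try:
                res = trimmer(g[value].to_numpy())
            except ValueError:      # cell too small to trim
                keep_idx.extend(g.index)
                continue
            keep_idx.extend(g.index[res.kept])
        kept = frame.loc[sorted(keep_idx)]
        report.append({"stage": name, "n_in": len(frame),
                       "n_removed": len(frame) - len(kept),
                       "pct_removed": 100.0 * (len(frame) - len(kept)) / len(frame)})
        return kept

    df = _stage(df, "iqr_1.5", iqr_trim)
    df = _stage(df, "mean_2sd", lambda v: sd_trim(v, one_sided=one_sided_sd))
    if drop_errors:
        n_in = len(df)
        df = df[df["accuracy"] == 1]
        report.append({"stage": "errors", "n_in": n_in,
                       "n_removed": n_in - len(df),
                       "pct_removed": 100.0 * (n_in - len(df)) / max(n_in, 1)})
    return df, pd.DataFrame(report)


# ---------------------------------------------------------------------
# Variance diagnostics
# ---------------------------------------------------------------------

def variance_diagnostics(trials: pd.DataFrame, value: str = "rt_ms",
                         subject: str = "participant",
                         by=("device", "n_back", "trial_type")) -> pd.DataFrame:
    """Two variance views per condition cell.

    ``var_of_means``: variance (ddof=1) across participants of the
    per-participant mean -- the between-subject spread feeding the
    ANOVA error terms.  ``mean_within_var``: mean across participants of
    the within-participant trial variance (ddof=1) -- the trial-level
    noise.  The first is shift-invariant per participant only through
    the means; the second exactly so.
    """
    by = list(by)
    df = trials[trials[value].notna()]
    rows = []
    for key, g in df.groupby(by, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        per = g.groupby(subject)[value]
        means = per.mean()
        wvars = per.var(ddof=1)
        rows.append({**dict(zip(by, key)),
                     "var_of_means": means.var(ddof=1),
                     "mean_within_var": wvars.mean()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# Repeated-measures / split-plot ANOVA
# ---------------------------------------------------------------------

def _center(arr: np.ndarray, axes) -> np.ndarray:
    """Sequentially center along each axis: leaves the highest-order
    interaction residual for those axes (balanced designs)."""
    for ax in axes:
        arr = arr - arr.mean(axis=ax, keepdims=True)
    return arr


def _gg_epsilon(d: np.ndarray, group_idx: np.ndarray, v_levels) -> float:
    """Greenhouse-Geisser epsilon for a within effect.

    ``d``: (n_subjects, k1, .., km) cell means over the effect's
    factors; covariance pooled within between-groups; contrasts are the
    Kronecker product of per-factor orthonormal (Helmert) contrasts.
    """
    n = d.shape[0]
    flat = d.reshape(n, -1)
    # pooled within-group covariance
    resid = flat - np.stack([flat[group_idx == g].mean(axis=0)
                             for g in group_idx])
    n_groups = len(np.unique(group_idx))
    dof = n - n_groups
    if dof < 1:
        return 1.0
    sigma = resid.T @ resid / dof
    C = np.array([[1.0]])
    for k in v_levels:
        C = np.kron(C, helmert(k, full=False))
    A = C @ sigma @ C.T
    m = A.shape[0]
    tr = np.trace(A)
    denom = m * np.sum(A * A)
    if denom <= 0:
        return 1.0
    eps = tr * tr / denom
    return float(min(1.0, max(1.0 / m, eps)))


def rm_anova(data: pd.DataFrame, dv: str, within, subject: str = "participant",
             between=()) -> pd.DataFrame:
    """Balanced repeated-measures (optionally split-plot) ANOVA.

    Parameters
    ----------
    data : DataFrame
        Long format; one value per subject x cell (multiple rows per
        cell are averaged first, the standard aggregation for RM
        designs).
    dv : str
        Dependent-variable column.
    within, between : list of str
        Within-subject and between-subject factor columns.  Every
        subject must have every within cell, belong to exactly one
        between cell, and between groups must be equally sized;
        otherwise :class:`DesignError`.
    subject : str
        Subject identifier column.

    Returns
    -------
    DataFrame with one row per effect: ``effect, SS, df1, df2, MS, F,
    p, partial_eta_sq, eps_gg, p_gg, error_SS``.  ``F`` is NaN (and
    flagged by a zero error SS) when the error stratum has no
    variance.  ``eps_gg``/``p_gg`` are populated for effects whose
    within part has >= 2 numerator df; elsewhere epsilon is exactly 1.
    """
    within = list(within)
    between = list(between)
    if not within and not between:
        raise DesignError("at least one factor required")
    factors = between + within

    agg = (data.groupby([subject] + factors, sort=True)[dv]
           .mean().reset_index())

    w_levels = {f: sorted(agg[f].unique()) for f in within}
    b_levels = {f: sorted(agg[f].unique()) for f in between}
    subjects = sorted(agg[subject].unique())
    n_subj = len(subjects)
    if n_subj < 2:
        raise DesignError("need at least 2 subjects")

    # subject -> between cell; must be unique per subject
    if between:
        smap = agg.groupby(subject)[between].nunique()
        if (smap > 1).any().any():
            raise DesignError("a subject appears in more than one between cell")
        sgroups = agg.groupby(subject)[between].first().loc[subjects]
        combos = list(itertools.product(*(b_levels[f] for f in between)))
        group_of = {s: combos.index(tuple(sgroups.loc[s])) for s in subjects}
        counts = np.bincount([group_of[s] for s in subjects], minlength=len(combos))
        if counts.min() == 0 or counts.min() != counts.max():
            raise DesignError("between groups must be non-empty and equally sized")
        n_groups, r = len(combos), int(counts[0])
    else:
        group_of = {s: 0 for s in subjects}
        n_groups, r = 1, n_subj
    group_idx = np.array([group_of[s] for s in subjects])

    # within-cell array Y[subject, w1, .., wd]
    wk = [len(w_levels[f]) for f in within]
    piv = agg.pivot_table(index=subject, columns=within or None, values=dv)
    if within:
        full_cols = (pd.MultiIndex.from_product([w_levels[f] for f in within])
                     if len(within) > 1 else pd.Index(w_levels[within[0]]))
        piv = piv.reindex(index=subjects, columns=full_cols)
    else:
        piv = piv.reindex(index=subjects)
    if piv.isna().any().any():
        raise DesignError("design not balanced: missing subject x cell values")
    Y = piv.to_numpy(float).reshape([n_subj] + wk)

    bk = [len(b_levels[f]) for f in between]
    k_of = dict(zip(factors, bk + wk))
    Kw = int(np.prod(wk)) if wk else 1

    # cell-means table M over between x within cells
    M = np.zeros(bk + wk)
    for gi in range(n_groups):
        sl = tuple(np.unravel_index(gi, bk)) if between else ()
        M[sl] = Y[group_idx == gi].mean(axis=0)

    axis_of = {f: i for i, f in enumerate(factors)}

    def effect_ss(S):
        other = [axis_of[f] for f in factors if f not in S]
        e = M.mean(axis=tuple(other), keepdims=True) if other else M
        e = _center(e, [axis_of[f] for f in S])
        scale = r * np.prod([k_of[f] for f in factors if f not in S])
        return float(scale * np.sum(e ** 2)), int(np.prod([k_of[f] - 1 for f in S]))

    # error strata
    sub_means = Y.reshape(n_subj, -1).mean(axis=1)
    grp_means = np.array([sub_means[group_idx == g].mean() for g in group_idx])
    ss_sub_within = float(Kw * np.sum((sub_means - grp_means) ** 2))
    df_sub_within = n_subj - n_groups

    def error_within(V):
        """SS and df of the V x subject(group) interaction stratum."""
        keep_axes = [1 + within.index(f) for f in V]       # axes in Y
        drop_axes = [1 + i for i in range(len(within)) if within[i] not in V]
        d = Y.mean(axis=tuple(drop_axes)) if drop_axes else Y
        ss = 0.0
        for g in range(n_groups):
            dg = d[group_idx == g]
            resid = _center(dg, [0] + list(range(1, dg.ndim)))
            ss += np.sum(resid ** 2)
        scale = np.prod([k_of[f] for f in within if f not in V])
        df = n_groups * (r - 1) * int(np.prod([k_of[f] - 1 for f in V]))
        return float(scale * ss), df, d

    rows = []
    # iterate effects: by order (mains, 2-way, ...) preserving factor order
    for size in range(1, len(factors) + 1):
        for S in itertools.combinations(factors, size):
            ss_eff, df1 = effect_ss(S)
            V = [f for f in S if f in within]
            if V:
                ss_err, df2, d = error_within(V)
            else:
                ss_err, df2 = ss_sub_within, df_sub_within
            ms_eff = ss_eff / df1 if df1 else np.nan
            ms_err = ss_err / df2 if df2 else np.nan
            if ss_err > 0 and df2 > 0:
                F = ms_eff / ms_err
                p = float(sps.f.sf(F, df1, df2))
            else:
                F, p = np.nan, np.nan   # zero error variance: F undefined
            peta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else np.nan
            df_v = int(np.prod([k_of[f] - 1 for f in V])) if V else 0
            if V and df_v >= 2 and np.isfinite(F):
                eps = _gg_epsilon(d, group_idx, [k_of[f] for f in V])
                p_gg = float(sps.f.sf(F, eps * df1, eps * df2))
            else:
                eps = 1.0 if V else np.nan
                p_gg = p
            rows.append({"effect": " * ".join(S), "SS": ss_eff, "df1": df1,
                         "df2": df2, "MS": ms_eff, "F": F, "p": p,
                         "partial_eta_sq": peta, "eps_gg": eps, "p_gg": p_gg,
                         "error_SS": ss_err})
    return pd.DataFrame(rows)


def posthoc_pairwise(data: pd.DataFrame, dv: str, factor: str,
                     subject: str = "participant",
                     correction: str = "holm") -> pd.DataFrame:
    """Paired t-tests between all level pairs of one within factor.

    Values are first averaged to participant x level means (collapsing
    other factors).  Returns per pair: mean difference (A - B), SE, t,
    raw and corrected p.  Pairs with zero-variance differences are
    flagged ``degenerate`` (SE = 0; t is 0 when the difference is also
    0, otherwise +/-inf and p = 0).
    """
    if correction not in ("holm", "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")
    piv = (data.groupby([subject, factor])[dv].mean().unstack(factor))
    if piv.isna().any().any():
        raise DesignError("every subject needs every level")
    levels = list(piv.columns)
    rows = []
    for a, b in itertools.combinations(levels, 2):
        diff = (piv[a] - piv[b]).to_numpy(float)
        n = diff.size
        if n < 2:
            raise DesignError("need at least 2 subjects per pair")
        m = diff.mean()
        se = diff.std(ddof=1) / np.sqrt(n)
        if se == 0:
            t = 0.0 if m == 0 else np.copysign(np.inf, m)
            p = 1.0 if m == 0 else 0.0
            degenerate = True
        else:
            t = m / se
            p = 2.0 * sps.t.sf(abs(t), n - 1)
            degenerate = False
        rows.append({"A": a, "B": b, "mean_diff": m, "SE": se, "t": t,
                     "df": n - 1, "p_uncorrected": p, "degenerate": degenerate})
    out = pd.DataFrame(rows)
    out["p_corrected"] = multipletests(out["p_uncorrected"], method=correction)[1]
    return out


# ---------------------------------------------------------------------
# Windowed conditional-accuracy inference
# ---------------------------------------------------------------------

def windowed_ca_table(events: pd.DataFrame, window_ms: float = 500.0,
                      n_windows: int = 8,
                      subject: str = "participant") -> pd.DataFrame:
    """Per-cell conditional accuracy in consecutive time windows.

    Windows are right-closed spans of ``window_ms`` from stimulus onset
    (an event at exactly 500 ms belongs to window 1).  CA is the mean
    crossing correctness per subject x N-back x trial type x spatial
    threshold x window; only non-empty cells appear, with the event
    count alongside.
    """
    ev = events[(events["t_ms"] > 0)
                & (events["t_ms"] <= n_windows * window_ms)].copy()
    ev["window"] = np.ceil(ev["t_ms"] / window_ms).astype(int)
    grp = ev.groupby([subject, "n_back", "trial_type", "threshold_index",
                      "window"], sort=True)
    out = grp["correct"].agg(ca="mean", n_events="size").reset_index()
    return out


def windowed_ca_anova(table: pd.DataFrame, subject: str = "participant",
                      spatial: str = "threshold_index") -> dict:
    """One TrialType x N-back RM-ANOVA per time window on CA values.

    Within each window the spatial bins enter as an additional
    within-subject repeated measure, so the model is a three-way
    fully-within ANOVA (trial type x N-back x spatial bin) with the
    subject as the random factor.  Spatial bins empty for *everyone*
    in a window are dropped from that window; subjects still missing
    any remaining cell are excluded from that window (and listed).
    No correction is applied across windows.

    Returns ``{window: {"anova": DataFrame | None, "excluded": [...],
    "n_subjects": int, "means": DataFrame}}`` where ``means`` holds the
    per-subject CA averaged over spatial bins for each condition -- the
    display values for a window-by-window accuracy figure.
    """
    cond_cells = ["trial_type", "n_back"]
    results = {}
    for win, sub in table.groupby("window", sort=True):
        means = (sub.groupby([subject] + cond_cells)["ca"]
                 .mean().reset_index())
        n_conds = sub.groupby(cond_cells).ngroups
        # coverage: does subject s have bin b in every condition?
        cov = (sub.groupby([subject, spatial])
               .apply(lambda g: g.groupby(cond_cells).ngroups == n_conds,
                      include_groups=False)
               .unstack(spatial, fill_value=False))
        # iteratively drop the worst-covered subject until some bins are
        # fully covered by everyone remaining
        keep = list(cov.index)
        while keep:
            full = cov.loc[keep].all(axis=0)
            if full.any():
                break
            scores = cov.loc[keep].sum(axis=1)
            keep.remove(scores.idxmin())
        usable_bins = (list(cov.columns[cov.loc[keep].all(axis=0)])
                       if keep else [])
        excluded = [s for s in sub[subject].unique() if s not in keep]
        entry = {"excluded": excluded, "n_subjects": len(keep),
                 "spatial_bins": usable_bins, "means": means, "anova": None}
        if len(keep) >= 2 and usable_bins and n_conds > 1:
            dat = sub[sub[subject].isin(keep)
                      & sub[spatial].isin(usable_bins)]
            try:
                entry["anova"] = rm_anova(dat, "ca",
                                          within=["trial_type", "n_back", spatial],
                                          subject=subject)
            except DesignError:
                entry["anova"] = None
        results[int(win)] = entry
    return results
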