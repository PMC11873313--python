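"""Trimming, variance diagnostics, RM-ANOVA, post-hocs, windowed CA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from stsa.stats import (DesignError, iqr_trim, sd_trim, trim_pipeline,
                        variance_diagnostics, rm_anova, posthoc_pairwise,
                        windowed_ca_table, windowed_ca_anova)


# ---------------------------------------------------------------------
# Trimming
# ---------------------------------------------------------------------

class TestIqrTrim:
    def test_textbook_fixture_drops_outlier(self):
        r = iqr_trim([1, 2, 3, 4, 100])
        assert r.values.tolist() == [1, 2, 3, 4]
        assert (r.lower, r.upper) == (-1.0, 7.0)
        assert r.pct_removed == pytest.approx(20.0)

    def test_constant_values_unchanged(self):
        r = iqr_trim([5.0] * 6)
        assert r.n_removed == 0

    def test_symmetric_data_unchanged(self):
        r = iqr_trim(np.arange(1, 21, dtype=float))
        assert r.n_removed == 0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            iqr_trim([1, 2, 3])


class TestSdTrim:
    def test_constant_values_unchanged(self):
        r = sd_trim([3.0, 3.0, 3.0])
        assert r.n_removed == 0

    def test_brute_force_bound_on_small_fixture(self):
        # mean 2, sd sqrt(20)~4.47: bounds [-6.94, 10.94] keep everything
        v = np.array([0, 0, 0, 0, 10.0])
        lo = v.mean() - 2 * v.std(ddof=1)
        hi = v.mean() + 2 * v.std(ddof=1)
        expected = v[(v >= lo) & (v <= hi)]
        r = sd_trim(v)
        assert r.values.tolist() == expected.tolist()
        assert r.n_removed == 0

    def test_normal_sample_keeps_about_95pct(self):
        rng = np.random.default_rng(11)
        r = sd_trim(rng.standard_normal(1000))
        assert 0.93 <= r.values.size / 1000 <= 0.97

    def test_one_sided_keeps_low_tail(self):
        v = np.array([-50, 0, 0, 0, 0, 0.0])
        assert sd_trim(v, one_sided=True).n_removed == 0
        assert sd_trim(v, one_sided=False).n_removed == 1

    def test_output_subset_and_second_pass_removes_no_more(self):
        rng = np.random.default_rng(4)
        v = rng.lognormal(6, 1, size=300)
        r1 = iqr_trim(v)
        assert set(r1.values).issubset(set(v))
        r2 = iqr_trim(r1.values)
        assert r2.n_removed <= r1.n_removed


def test_trim_pipeline_accounting_relative_to_previous_stage():
    rng = np.random.default_rng(0)
    trials = pd.DataFrame({
        "participant": "P1",
        "device": "vr", "n_back": 1, "trial_type": "match",
        "rt_ms": rng.lognormal(6.5, 0.6, size=400),
        "accuracy": rng.integers(0, 2, size=400),
    })
    kept, report = trim_pipeline(trials, drop_errors=True)
    assert report["stage"].tolist() == ["iqr_1.5", "mean_2sd", "errors"]
    n_in = [400, 400 - report["n_removed"][0],
            400 - report["n_removed"][0] - report["n_removed"][1]]
    assert report["n_in"].tolist() == n_in
    for _, row in report.iterrows():
        assert row["pct_removed"] == pytest.approx(
            100 * row["n_removed"] / row["n_in"])
    assert len(kept) == n_in[2] - report["n_removed"].iloc[2]


# ---------------------------------------------------------------------
# Variance diagnostics
# ---------------------------------------------------------------------

class TestVarianceDiagnostics:
    def _table(self, values_by_participant):
        rows = []
        for p, vals in values_by_participant.items():
            for v in vals:
                rows.append({"participant": p, "device": "vr", "n_back": 1,
                             "trial_type": "match", "rt_ms": v})
        return pd.DataFrame(rows)

    def test_identical_constants_give_zero(self):
        d = variance_diagnostics(self._table({"P1": [5, 5], "P2": [5, 5]}))
        assert d["var_of_means"][0] == 0 and d["mean_within_var"][0] == 0

    def test_variance_of_two_means(self):
        d = variance_diagnostics(self._table({"P1": [1, 1], "P2": [3, 3]}))
        assert d["var_of_means"][0] == pytest.approx(2.0)   # n-1 denominator

    def test_within_variance_shift_invariant(self):
        base = {"P1": [1.0, 2, 3], "P2": [4.0, 5, 9]}
        shifted = {p: [v + 10 * i for v in vals]
                   for i, (p, vals) in enumerate(base.items())}
        a = variance_diagnostics(self._table(base))
        b = variance_diagnostics(self._table(shifted))
        assert a["mean_within_var"][0] == pytest.approx(b["mean_within_var"][0])


# ---------------------------------------------------------------------
# RM-ANOVA
# ---------------------------------------------------------------------

def brute_force_within_anova(df, dv, within, subject):
    """Explicit mean/SS arithmetic for a fully-within design (oracle).

    Written as literal loops over cells -- independent of the package's
    inclusion-exclusion implementation.
    """
    subs = sorted(df[subject].unique())
    levels = {f: sorted(df[f].unique()) for f in within}
    grand = df[dv].mean()
    n = len(subs)

    def cell_mean(**kw):
        m = np.ones(len(df), dtype=bool)
        for k, v in kw.items():
            m &= df[k] == v
        return df.loc[m, dv].mean()

    out = {}
    for r in range(1, len(within) + 1):
        for S in itertools.combinations(within, r):
            ss = 0.0
            for combo in itertools.product(*(levels[f] for f in S)):
                # inclusion-exclusion over subsets of S
                eff = 0.0
                for rr in range(len(S) + 1):
                    for T in itertools.combinations(range(len(S)), rr):
                        mean_T = (cell_mean(**{S[i]: combo[i] for i in T})
                                  if T else grand)
                        eff += (-1) ** (len(S) - rr) * mean_T
                weight = n * np.prod([len(levels[f]) for f in within
                                      if f not in S])
                ss += weight * eff ** 2
            # error: interaction of the effect with subjects
            ss_err = 0.0
            for s in subs:
                for combo in itertools.product(*(levels[f] for f in S)):
                    resid = 0.0
                    for rr in range(len(S) + 1):
                        for T in itertools.combinations(range(len(S)), rr):
                            kw = {S[i]: combo[i] for i in T}
                            m_with = cell_mean(subject=None, **kw) if False else None
                            # means with and without the subject restriction
                            sel = np.ones(len(df), dtype=bool)
                            for k, v in kw.items():
                                sel &= df[k] == v
                            m_all = df.loc[sel, dv].mean()
                            m_sub = df.loc[sel & (df[subject] == s), dv].mean()
                            resid += (-1) ** (len(S) - rr) * (m_sub - m_all)
                    weight = np.prod([len(levels[f]) for f in within
                                      if f not in S])
                    ss_err += weight * resid ** 2
            df1 = int(np.prod([len(levels[f]) - 1 for f in S]))
            df2 = (n - 1) * df1
            out[" * ".join(S)] = (ss, df1, ss_err, df2,
                                  (ss / df1) / (ss_err / df2))
    return out


@pytest.fixture(scope="module")
def six_by_2x3():
    rng = np.random.default_rng(8)
    rows = []
    for s in range(6):
        subj_off = rng.normal(0, 1)
        for a in ("a1", "a2"):
            for b in ("b1", "b2", "b3"):
                rows.append({"participant": f"S{s}", "A": a, "B": b,
                             "y": rng.normal() + subj_off
                             + 0.8 * (a == "a2") + 0.3 * int(b[1])})
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_matches_brute_force_ss_decomposition(self, six_by_2x3):
        res = rm_anova(six_by_2x3, "y", within=["A", "B"],
                       subject="participant").set_index("effect")
        oracle = brute_force_within_anova(six_by_2x3, "y", ["A", "B"],
                                          "participant")
        for eff, (ss, df1, ss_err, df2, F) in oracle.items():
            row = res.loc[eff]
            assert row["SS"] == pytest.approx(ss, abs=1e-8)
            assert row["error_SS"] == pytest.approx(ss_err, abs=1e-8)
            assert (row["df1"], row["df2"]) == (df1, df2)
            assert row["F"] == pytest.approx(F, abs=1e-8)

    def test_two_level_factor_equals_squared_paired_t(self, six_by_2x3):
        from scipy import stats as sps
        res = rm_anova(six_by_2x3, "y", within=["A"], subject="participant")
        piv = (six_by_2x3.groupby(["participant", "A"])["y"].mean()
               .unstack("A"))
        t, p = sps.ttest_rel(piv["a2"], piv["a1"])
        assert res["F"][0] == pytest.approx(t ** 2, rel=1e-10)
        assert res["p"][0] == pytest.approx(p, rel=1e-10)

    def test_two_level_factor_epsilon_is_one(self, six_by_2x3):
        res = rm_anova(six_by_2x3, "y", within=["A"], subject="participant")
        assert res["eps_gg"][0] == 1.0

    def test_matches_pingouin_including_gg(self, six_by_2x3):
        pg = pytest.importorskip("pingouin")
        ref = pg.rm_anova(data=six_by_2x3, dv="y", within=["A", "B"],
                          subject="participant", detailed=True)
        res = rm_anova(six_by_2x3, "y", within=["A", "B"],
                       subject="participant")
        for i, src in enumerate(["A", "B", "A * B"]):
            row = res[res["effect"] == src].iloc[0]
            refrow = ref[ref["Source"] == src].iloc[0]
            assert row["F"] == pytest.approx(refrow["F"], rel=1e-9)
            assert row["p"] == pytest.approx(refrow["p_unc"], rel=1e-9)
            assert row["eps_gg"] == pytest.approx(refrow["eps"], rel=1e-6)

    def test_three_within_factors_df_shapes_match_19_subjects(self):
        # 19 subjects, 2x3x2 fully within: df shapes (1,18) and (2,36)
        rng = np.random.default_rng(1)
        rows = [{"participant": f"P{s}", "device": d, "n_back": n,
                 "trial_type": tt, "y": rng.normal()}
                for s in range(19) for d in ("classical", "vr")
                for n in (1, 2, 3) for tt in ("match", "nonmatch")]
        res = rm_anova(pd.DataFrame(rows), "y",
                       within=["device", "n_back", "trial_type"],
                       subject="participant").set_index("effect")
        assert tuple(res.loc["device", ["df1", "df2"]]) == (1, 18)
        assert tuple(res.loc["n_back", ["df1", "df2"]]) == (2, 36)
        assert tuple(res.loc["device * n_back", ["df1", "df2"]]) == (2, 36)

    def test_split_plot_matches_pingouin_mixed(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        rows = [{"participant": f"{g}{s}", "G": g, "B": f"b{b}",
                 "y": rng.normal() + 0.4 * (g == "trt") * b}
                for g in ("ctl", "trt") for s in range(6) for b in range(3)]
        df = pd.DataFrame(rows)
        res = rm_anova(df, "y", within=["B"], between=["G"],
                       subject="participant").set_index("effect")
        ref = pg.mixed_anova(data=df, dv="y", within="B", between="G",
                             subject="participant").set_index("Source")
        assert res.loc["G", "F"] == pytest.approx(ref.loc["G", "F"], rel=1e-9)
        assert res.loc["B", "F"] == pytest.approx(ref.loc["B", "F"], rel=1e-9)
        assert res.loc["G * B", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9)

    def test_partial_eta_sq_identity(self, six_by_2x3):
        res = rm_anova(six_by_2x3, "y", within=["A", "B"],
                       subject="participant")
        for _, row in res.iterrows():
            assert row["partial_eta_sq"] == pytest.approx(
                row["SS"] / (row["SS"] + row["error_SS"]))

    def test_unbalanced_rejected(self, six_by_2x3):
        with pytest.raises(DesignError):
            rm_anova(six_by_2x3.iloc[:-1], "y", within=["A", "B"],
                     subject="participant")

    def test_zero_error_variance_signalled(self):
        rows = [{"participant": f"P{s}", "A": a, "y": float(a == "a2")}
                for s in range(5) for a in ("a1", "a2")]
        res = rm_anova(pd.DataFrame(rows), "y", within=["A"],
                       subject="participant")
        assert np.isnan(res["F"][0]) and res["error_SS"][0] == 0

    def test_type_one_error_rate_near_nominal(self):
        # null 2x3 within tables: rejection rate at alpha=.05 in [.03,.07]
        rng = np.random.default_rng(2024)
        reject, total = 0, 0
        reps = 500
        for _ in range(reps):
            y = rng.standard_normal(10 * 6)
            df = pd.DataFrame({
                "participant": np.repeat(np.arange(10), 6),
                "A": np.tile(np.repeat(["a1", "a2"], 3), 10),
                "B": np.tile(["b1", "b2", "b3"], 20),
                "y": y,
            })
            res = rm_anova(df, "y", within=["A", "B"], subject="participant")
            reject += int((res["p"] < 0.05).sum())
            total += len(res)
        assert 0.03 <= reject / total <= 0.07


class TestPosthoc:
    def test_identical_conditions_zero_difference(self):
        rows = [{"participant": f"P{s}", "A": a, "y": s * 1.0}
                for s in range(5) for a in ("a1", "a2")]
        res = posthoc_pairwise(pd.DataFrame(rows), "y", "A")
        assert res["mean_diff"][0] == 0 and res["t"][0] == 0
        assert res["degenerate"][0]

    def test_pure_shift_degenerate_se(self):
        rows = [{"participant": f"P{s}", "A": a, "y": s + 2.0 * (a == "a2")}
                for s in range(5) for a in ("a1", "a2")]
        res = posthoc_pairwise(pd.DataFrame(rows), "y", "A")
        assert res["SE"][0] == 0 and res["degenerate"][0]
        assert abs(res["mean_diff"][0]) == pytest.approx(2.0)

    def test_matches_brute_force_paired_t(self):
        from scipy import stats as sps
        rng = np.random.default_rng(9)
        rows = [{"participant": f"P{s}", "A": a,
                 "y": rng.normal() + 0.5 * (a == "a3")}
                for s in range(12) for a in ("a1", "a2", "a3")]
        df = pd.DataFrame(rows)
        res = posthoc_pairwise(df, "y", "A", correction="bonferroni")
        piv = df.pivot_table(index="participant", columns="A", values="y")
        for _, row in res.iterrows():
            t, p = sps.ttest_rel(piv[row["A"]], piv[row["B"]])
            assert row["t"] == pytest.approx(t, abs=1e-10)
            assert row["p_uncorrected"] == pytest.approx(p, abs=1e-10)
            assert row["p_corrected"] == pytest.approx(min(1.0, 3 * p),
                                                       abs=1e-10)


# ---------------------------------------------------------------------
# Windowed CA inference
# ---------------------------------------------------------------------

def _ca_table(rng, n_subj=20, n_bins=4, effect_window=None, d=0.0):
    """Constructed CA table: known ground truth per window."""
    rows = []
    for s in range(n_subj):
        subj_off = rng.normal(0, 0.05)
        for w in range(1, 9):
            for tt in ("match", "nonmatch"):
                for n in (1, 2, 3):
                    for b in range(1, n_bins + 1):
                        mu = 0.7 + subj_off
                        if w == effect_window and tt == "match":
                            mu += d * 0.1   # d in units of the 0.1 noise SD
                        rows.append({"participant": f"P{s:02d}", "window": w,
                                     "trial_type": tt, "n_back": n,
                                     "threshold_index": b,
                                     "ca": rng.normal(mu, 0.1),
                                     "n_events": 5})
    return pd.DataFrame(rows)


class TestWindowedCa:
    def test_table_window_assignment_right_closed(self):
        ev = pd.DataFrame({
            "participant": ["P1"] * 3, "n_back": [1] * 3,
            "trial_type": ["match"] * 3, "threshold_index": [1, 1, 1],
            "t_ms": [500.0, 500.1, 3999.9], "correct": [True, False, True],
        })
        tab = windowed_ca_table(ev)
        assert tab.set_index("window")["ca"].to_dict() == {1: 1.0, 2: 0.0,
                                                           8: 1.0}

    def test_injected_effect_detected_only_in_its_window(self):
        # TrialType effect of d=1.5 injected in window 1 only: detected
        # there with high power, nowhere else beyond chance
        reps, alpha = 30, 0.05
        hits, false_pos, others = 0, 0, 0
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            tab = _ca_table(rng, effect_window=1, d=1.5)
            res = windowed_ca_anova(tab)
            for w, entry in res.items():
                p = entry["anova"].set_index("effect").loc["trial_type", "p"]
                if w == 1:
                    hits += int(p < alpha)
                else:
                    others += 1
                    false_pos += int(p < alpha)
        assert hits / reps >= 0.9
        assert false_pos / others <= 0.12

    def test_identical_ca_everywhere_f_undefined(self):
        rng = np.random.default_rng(0)
        tab = _ca_table(rng)
        tab["ca"] = 0.7
        res = windowed_ca_anova(tab)
        for entry in res.values():
            assert entry["anova"] is None or np.isnan(
                entry["anova"]["F"]).all()

    def test_subjects_with_missing_cells_excluded_and_logged(self):
        rng = np.random.default_rng(5)
        tab = _ca_table(rng, n_subj=6)
        # P00 loses all nonmatch data in window 3
        drop = (tab["participant"] == "P00") & (tab["window"] == 3) \
            & (tab["trial_type"] == "nonmatch")
        res = windowed_ca_anova(tab[~drop])
        assert "P00" in res[3]["excluded"]
        assert res[3]["n_subjects"] == 5
        assert res[2]["excluded"] == []
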