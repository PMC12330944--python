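"""Cox screening, Kaplan-Meier/log-rank, paired and trend tests, adverse score."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prostaxis.prognostics import (
    CollinearityError,
    adverse_feature_score,
    bh_adjust,
    cochran_armitage_trend,
    cox_fit,
    km_logrank,
    multivariable_fit,
    select_analysis_samples,
    univariate_screen,
    wilcoxon_signed_rank,
)

# ---------------------------------------------------------------- sample pick


class TestSelectAnalysisSamples:
    META = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4", "s5", "s6"],
            "patient_id": ["p1", "p1", "p2", "p2", "p3", "p3"],
            "timepoint": ["pre", "on_treatment", "pre", "pre", "on_treatment", "progression"],
            "biopsy_order": [1, 2, 2, 1, 1, 2],
        }
    )

    def test_pre_sample_retained_over_on_treatment(self):
        out = select_analysis_samples(self.META)
        assert out.loc[out.patient_id == "p1", "sample_id"].tolist() == ["s1"]

    def test_earliest_of_multiple_pre_samples(self):
        out = select_analysis_samples(self.META)
        assert out.loc[out.patient_id == "p2", "sample_id"].tolist() == ["s4"]

    def test_patient_without_pre_sample_excluded(self):
        out = select_analysis_samples(self.META)
        assert "p3" not in set(out.patient_id)
        assert len(out) == 2


# ----------------------------------------------------------------------- cox


TOY = pd.DataFrame(
    {
        "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        "event": [1, 1, 0, 1, 0, 1],
        "x": [1.0, 0.0, 1.0, 1.0, 0.0, 0.0],
    }
)


def toy_partial_loglik(beta: np.ndarray) -> np.ndarray:
    """Written-out partial likelihood of the 6-record toy set (no ties)."""
    t = TOY["time"].to_numpy()
    d = TOY["event"].to_numpy()
    x = TOY["x"].to_numpy()
    beta = np.atleast_1d(beta)[:, None]
    ll = np.zeros(beta.shape[0])
    for i in range(len(t)):
        if d[i]:
            risk = x[t >= t[i]]
            ll += beta[:, 0] * x[i] - np.log(np.exp(beta * risk).sum(axis=1))
    return ll


class TestCoxFit:
    def test_toy_matches_grid_maximizer(self):
        grid = np.arange(-5.0, 5.0, 1e-4)
        beta_grid = grid[np.argmax(toy_partial_loglik(grid))]
        res = cox_fit(TOY, ["x"], strata_col=None)
        assert abs(res["x"]["beta"] - beta_grid) <= 1e-4

    def test_matches_lifelines_with_strata_and_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(0)
        n = 250
        df = pd.DataFrame(
            {
                "x1": rng.standard_normal(n),
                "x2": rng.standard_normal(n),
                "cohort": rng.choice(["A", "B", "C"], n),
            }
        )
        lp = 0.8 * df.x1 - 0.5 * df.x2
        t = rng.exponential(np.exp(-lp))
        c = rng.exponential(2.0, n)
        df["time"] = np.ceil(np.minimum(t, c) * 4)  # induces ties
        df["event"] = (t <= c).astype(int)
        mine = cox_fit(df, ["x1", "x2"], strata_col="cohort")
        ref = CoxPHFitter().fit(
            df[["x1", "x2", "time", "event", "cohort"]],
            "time",
            "event",
            strata=["cohort"],
        )
        assert np.abs(
            mine.summary["beta"].to_numpy() - ref.params_.to_numpy()
        ).max() < 1e-5
        assert np.abs(
            mine.summary["se"].to_numpy() - ref.standard_errors_.to_numpy()
        ).max() < 1e-5

    def test_efron_equals_breslow_without_ties(self):
        rng = np.random.default_rng(1)
        n = 120
        df = pd.DataFrame({"x": rng.standard_normal(n)})
        df["time"] = rng.exponential(np.exp(-0.5 * df.x))
        df["event"] = 1
        e = cox_fit(df, ["x"], strata_col=None, ties="efron")
        b = cox_fit(df, ["x"], strata_col=None, ties="breslow")
        assert abs(e["x"]["beta"] - b["x"]["beta"]) < 1e-8

    def test_null_covariate_near_zero(self):
        rng = np.random.default_rng(2)
        n = 500
        df = pd.DataFrame({"x": rng.standard_normal(n)})
        df["time"] = rng.exponential(1.0, n)
        df["event"] = (rng.random(n) < 0.8).astype(int)
        res = cox_fit(df, ["x"], strata_col=None)
        assert abs(res["x"]["beta"]) < 0.15

    def test_duplicated_covariate_collinearity_error(self):
        df = TOY.assign(x2=TOY["x"])
        with pytest.raises(CollinearityError):
            cox_fit(df, ["x", "x2"], strata_col=None)

    def test_eventless_stratum_dropped_with_warning(self):
        df = pd.concat(
            [
                TOY.assign(cohort="A"),
                TOY.assign(cohort="B", event=0),
            ],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="no events"):
            res = cox_fit(df, ["x"], strata_col="cohort")
        assert res.n == 6


# -------------------------------------------------------------------- screen


class TestScreenAndBH:
    def test_bh_single_test_identity(self):
        assert bh_adjust([0.037]).tolist() == [0.037]

    def test_bh_stepup_hand_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_bh_monotone_and_bounded(self, rng):
        p = rng.random(40)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj <= 1.0).all() and (adj >= p - 1e-12).all()

    def test_screen_flags_linked_pathway(self, small_cohort, small_config):
        from prostaxis.synthetic_cohort import generate_survival

        expr, meta, act = small_cohort
        surv = generate_survival(act, meta, small_config)
        pat = meta.set_index("sample_id")["patient_id"]
        scores = pd.DataFrame(
            {
                "linked": act["proliferation"],
                "noise": np.random.default_rng(0).standard_normal(len(act)),
            }
        ).T.rename(columns=pat)
        table = univariate_screen(scores, surv)
        assert bool(table.loc["linked", "significant"])
        assert table.loc["linked", "direction"] == "adverse"
        assert not bool(table.loc["noise", "significant"])
        assert table["q"].min() >= 0.0 and (table["q"] >= table["p"]).all()


class TestMultivariable:
    def test_only_linked_axis_significant(self):
        from prostaxis.validation import multivariable_recovery

        rec = multivariable_recovery(n_seeds=5, seed0=3)
        assert rec["success"].all()
        assert abs(rec["beta_NEPC"].mean() - 1.0) <= 0.15

    def test_duplicated_axis_collinearity(self, small_cohort, small_config):
        from prostaxis.synthetic_cohort import generate_survival

        expr, meta, act = small_cohort
        surv = generate_survival(act, meta, small_config)
        pat = meta.set_index("sample_id")["patient_id"]
        comp = pd.DataFrame(
            {"A": act["nepc"], "B": act["nepc"]}
        ).T.rename(columns=pat)
        with pytest.raises(CollinearityError):
            multivariable_fit(comp, surv)


# ------------------------------------------------------------- km / log-rank


class TestKmLogrank:
    def test_identical_groups_null(self):
        base = pd.DataFrame(
            {"time": [1.0, 2.0, 3.0, 4.0], "event": [1, 0, 1, 1]},
            index=["a1", "a2", "a3", "a4"],
        )
        d = pd.concat([base, base.set_index(pd.Index(["b1", "b2", "b3", "b4"]))])
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=d.index)
        res = km_logrank(d, groups)
        assert res.chi2 < 1e-10
        assert np.isclose(res.p, 1.0)

    def test_two_group_statistic_hand_computed(self):
        d = pd.DataFrame(
            {"time": [1.0, 3.0, 5.0, 2.0, 4.0, 6.0], "event": [1] * 6},
            index=[f"i{k}" for k in range(6)],
        )
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=d.index)
        # manual O-E and hypergeometric variance sums over event times
        at_risk = {"A": 3, "B": 3}
        o_minus_e = 0.0
        var = 0.0
        for t, g in sorted(zip(d["time"], groups)):
            n = at_risk["A"] + at_risk["B"]
            o_minus_e += (g == "A") - at_risk["A"] / n
            if n > 1:
                var += at_risk["A"] * at_risk["B"] * (n - 1) / (n**2 * (n - 1))
            at_risk[g] -= 1
        expected_chi2 = o_minus_e**2 / var
        res = km_logrank(d, groups)
        assert abs(res.chi2 - expected_chi2) < 1e-10

    def test_km_without_censoring_is_empirical_survival(self):
        d = pd.DataFrame(
            {"time": [1.0, 3.0, 5.0, 2.0, 4.0, 6.0], "event": [1] * 6},
            index=[f"i{k}" for k in range(6)],
        )
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=d.index)
        curve = km_logrank(d, groups).curves["A"].set_index("time")["survival"]
        assert np.allclose(curve.loc[[1.0, 3.0, 5.0]], [2 / 3, 1 / 3, 0.0])

    def test_single_group_rejected(self):
        d = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 1]}, index=["a", "b"])
        with pytest.raises(ValueError, match="2 groups"):
            km_logrank(d, pd.Series(["A", "A"], index=d.index))


# ------------------------------------------------------------------ wilcoxon


class TestWilcoxon:
    def test_all_positive_n6_exact(self):
        before = np.zeros(6)
        after = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        w, p = wilcoxon_signed_rank(before, after)
        assert w == 21.0  # sum of ranks 1..6
        assert np.isclose(p, 2 / 64)  # two-tailed: 2 x 1/2^6

    def test_single_nonzero_difference(self):
        before = np.array([1.0, 2.0, 3.0])
        after = np.array([1.0, 2.0, 5.0])
        w, _ = wilcoxon_signed_rank(before, after)
        assert w == 1.0

    def test_exact_matches_sign_enumeration(self):
        rng = np.random.default_rng(8)
        before = rng.standard_normal(10)
        after = before + rng.standard_normal(10)
        w, p = wilcoxon_signed_rank(before, after)
        # independent oracle: enumerate all 2^10 sign assignments
        diff = after - before
        ranks = stats.rankdata(np.abs(diff))
        w_obs = ranks[diff > 0].sum()
        sums = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([0, 1], repeat=10)
        ]
        sums = np.asarray(sums)
        p_oracle = min(
            1.0,
            2 * min(np.mean(sums >= w_obs - 1e-9), np.mean(sums <= w_obs + 1e-9)),
        )
        assert w == w_obs
        assert np.isclose(p, p_oracle)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(9)
        before = rng.standard_normal(40)
        after = before + 0.8 + rng.standard_normal(40) * 0.3
        _, p = wilcoxon_signed_rank(before, after)
        assert p < 1e-5

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank(np.ones(5), np.ones(5))


# ---------------------------------------------------------- cochran-armitage


class TestCochranArmitage:
    def test_monotone_table_closed_form(self):
        # counts 0/1/2 with 10/5/0 responders of 10 each
        score = np.repeat([0, 1, 2], 10)
        resp = np.concatenate([np.ones(10), np.ones(5), np.zeros(5), np.zeros(10)])
        res = cochran_armitage_trend(resp, score)
        # hand-derived: T = 5 - 15 = -10; Var = 0.25 * (50 - 900/30) = 5
        assert abs(res.z - (-10.0 / np.sqrt(5.0))) < 1e-10

    def test_asymptotic_close_to_permutation(self):
        rng = np.random.default_rng(4)
        score = rng.integers(0, 5, 60)
        resp = (rng.random(60) < 1 / (1 + np.exp(-(0.5 - 0.4 * score)))).astype(float)
        res = cochran_armitage_trend(resp, score, n_perm=10000, seed=0)
        assert abs(res.p - res.p_perm) <= 0.02

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            cochran_armitage_trend(np.ones(10), np.repeat([0, 1], 5))


# ------------------------------------------------------------- adverse score


def _composites(values: dict) -> pd.DataFrame:
    return pd.DataFrame(values).T


class TestAdverseFeatures:
    REF = _composites(
        {
            "Luminal_AR": np.arange(1.0, 10.0),
            "Proliferation": np.arange(1.0, 10.0),
            "mTOR_glycolysis": np.arange(1.0, 10.0),
            "NEPC": np.arange(1.0, 10.0),
        }
    )

    def test_median_patient_has_no_adverse_features(self):
        prof = adverse_feature_score(self.REF)
        mid = prof.table.iloc[4]  # all four axes at the reference median (5.0)
        assert mid["count"] == 0
        assert mid["group"] == "0"

    def test_luminal_minimum_alone_counts_one(self):
        comp = self.REF.copy()
        patient = comp.columns[4]
        comp.loc["Luminal_AR", patient] = 0.0  # below the whole reference
        prof = adverse_feature_score(comp)
        row = prof.table.loc[patient]
        assert row["count"] == 1
        assert row["group"] == "1-2"
        assert bool(row["Luminal_AR_low"])

    @pytest.mark.parametrize("m", [2, 4, 7])
    def test_balanced_tertiles_on_continuous_reference(self, m):
        rng = np.random.default_rng(m)
        vals = rng.standard_normal(3 * m)
        comp = _composites(
            {
                "Luminal_AR": vals,
                "Proliferation": vals,
                "mTOR_glycolysis": vals,
                "NEPC": vals,
            }
        )
        prof = adverse_feature_score(comp)
        assert int(prof.table["Luminal_AR_low"].sum()) == m
        assert int(prof.table["Proliferation_high"].sum()) == m

    def test_group_mapping_total(self):
        prof = adverse_feature_score(self.REF)
        counts = prof.table["count"]
        groups = prof.table["group"].astype(str)
        assert counts.between(0, 4).all()
        expected = np.select(
            [counts == 0, counts <= 2], ["0", "1-2"], default="3-4"
        )
        assert (groups.to_numpy() == expected).all()

    def test_small_reference_rejected(self):
        tiny = self.REF.iloc[:, :2]
        with pytest.raises(ValueError, match="at least 3"):
            adverse_feature_score(tiny)

    def test_missing_axis_rejected(self):
        with pytest.raises(ValueError, match="NEPC"):
            adverse_feature_score(self.REF.drop(index="NEPC"))
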