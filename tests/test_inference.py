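"""Statistical inference chain: screens, factorial effects, FDR control,
backward elimination, path analysis, marginal means."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import statsmodels.api as sm

from nirsnet.inference import (
    PathModel,
    PathModelSpec,
    backward_regression,
    bh_adjust,
    estimated_marginal_means,
    factorial_effects,
    normality_screen,
    variance_homogeneity,
)


def brute_force_bh(p, q=0.05):
    """Independent step-up oracle, straight from the definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, sorted_p[i] * m / (i + 1))
        adj[i] = running
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out, out <= q


def make_factorial(rng, n_per_cell=8, skill_delta=0.0, sd=1.0):
    rows = []
    sid = 0
    for skill in ("expert", "novice"):
        for sim in ("physical", "vr"):
            mu = skill_delta if skill == "expert" else 0.0
            for _ in range(n_per_cell):
                rows.append(dict(subject=f"S{sid}", skill=skill, simulator=sim,
                                 dv=rng.normal(mu, sd)))
                sid += 1
    return pd.DataFrame(rows)


class TestNormalityScreen:
    def test_gaussian_pvalues_roughly_uniform(self, rng):
        ps = []
        for _ in range(100):
            df = pd.DataFrame({"v": rng.standard_normal(50)})
            ps.append(normality_screen(df)["p"].iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_skewed_samples_detected(self, rng):
        hits = 0
        for _ in range(40):
            df = pd.DataFrame({"v": rng.exponential(1.0, 50)})
            if normality_screen(df)["p"].iloc[0] < 0.05:
                hits += 1
        assert hits >= 38  # >= 95%

    def test_constant_sample_flagged(self):
        out = normality_screen(pd.DataFrame({"v": np.ones(10)}))
        assert out["flagged"].iloc[0]
        assert np.isnan(out["W"].iloc[0])


class TestVarianceHomogeneity:
    def test_identical_groups_give_zero_statistic(self):
        v = np.tile([1.0, 2.0, 3.0, 4.0], 2)
        g = np.repeat(["a", "b"], 4)
        stat, _ = variance_homogeneity(v, g)
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_unequal_variances_detected(self, rng):
        hits = 0
        for _ in range(30):
            v = np.concatenate([rng.normal(0, 1, 50), rng.normal(0, 2, 50)])
            g = np.repeat(["a", "b"], 50)
            if variance_homogeneity(v, g)[1] < 0.05:
                hits += 1
        assert hits >= 27  # >= 90% power at a 4x variance ratio

    def test_single_observation_groups_rejected(self):
        with pytest.raises(ValueError):
            variance_homogeneity(np.array([1.0, 2.0]), np.array(["a", "b"]))


class TestFactorialEffects:
    def test_constant_dv_gives_zero_f(self, rng):
        df = make_factorial(rng)
        df["dv"] = 5.0
        tab = factorial_effects(df, "dv")
        assert np.allclose(tab.loc[["skill", "simulator", "skill:simulator"], "F"], 0.0)
        assert np.allclose(tab.loc[["skill", "simulator", "skill:simulator"], "partial_eta_sq"], 0.0)

    def test_partial_eta_sq_recomputable_from_ss(self, rng):
        df = make_factorial(rng, skill_delta=0.8)
        tab = factorial_effects(df, "dv")
        ss_err = tab.loc["Residual", "SS"]
        for eff in ("skill", "simulator", "skill:simulator"):
            expected = tab.loc[eff, "SS"] / (tab.loc[eff, "SS"] + ss_err)
            assert tab.loc[eff, "partial_eta_sq"] == pytest.approx(expected, rel=1e-12)

    def test_skill_main_effect_detected_most_strongly(self, rng):
        hits = 0
        for _ in range(40):
            df = make_factorial(rng, n_per_cell=8, skill_delta=1.0)
            tab = factorial_effects(df, "dv")
            ps = tab.loc[["skill", "simulator", "skill:simulator"], "p"]
            if ps.idxmin() == "skill":
                hits += 1
        assert hits >= 36  # >= 90%

    def test_null_pvalues_uniform(self, rng):
        ps = []
        for _ in range(200):
            df = make_factorial(rng, n_per_cell=6)
            ps.append(factorial_effects(df, "dv").loc["skill", "p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_empty_cell_rejected(self, rng):
        df = make_factorial(rng)
        df = df[~((df.skill == "expert") & (df.simulator == "vr"))]
        with pytest.raises(ValueError, match="cell"):
            factorial_effects(df, "dv")

    def test_trial_mean_policy_aggregates(self, rng):
        df = make_factorial(rng, n_per_cell=4)
        df = pd.concat([df.assign(trial=0), df.assign(trial=1, dv=df.dv + 0.1)],
                       ignore_index=True)
        tab_mean = factorial_effects(df, "dv", "trial-mean")
        assert tab_mean.loc["Residual", "df"] == 16 - 4
        tab_rep = factorial_effects(df, "dv", "trial-as-replicate")
        assert tab_rep.loc["Residual", "df"] == 32 - 4


class TestBHAdjust:
    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = np.round(rng.uniform(0, 1, m), int(rng.integers(1, 6)))
            adj, rej = bh_adjust(p)
            badj, brej = brute_force_bh(p)
            assert np.allclose(adj, badj, atol=1e-12)
            assert np.array_equal(rej, brej)

    def test_textbook_ladder_all_rejected(self):
        adj, rej = bh_adjust([0.01, 0.02, 0.03, 0.04, 0.05], q=0.05)
        assert np.allclose(adj, 0.05)
        assert rej.all()

    def test_all_ones_none_rejected(self):
        adj, rej = bh_adjust([1.0, 1.0, 1.0])
        assert not rej.any()

    def test_single_pvalue_unchanged(self):
        adj, rej = bh_adjust([0.04], q=0.05)
        assert adj[0] == pytest.approx(0.04)
        assert rej[0]

    def test_monotone_and_prefix_rejections(self, rng):
        p = rng.uniform(0, 1, 30)
        adj, rej = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        # rejections form a prefix of the sorted p-values
        flags = rej[order]
        assert not np.any(np.diff(flags.astype(int)) > 0)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestBackwardRegression:
    def test_true_predictor_retained(self, rng):
        kept_x1 = only_x1 = 0
        for _ in range(100):
            X = pd.DataFrame(rng.standard_normal((200, 3)), columns=["x1", "x2", "x3"])
            y = 2 * X["x1"] + rng.normal(0, 0.5, 200)
            res = backward_regression(y, X)
            kept_x1 += "x1" in res.retained
            only_x1 += res.retained == ["x1"]
        assert kept_x1 == 100
        # each noise predictor survives the final check with probability
        # ~removal_p, so the only-x1 rate is ~(1 - 0.1)^2 ~ 0.81
        assert only_x1 >= 75

    def test_pure_noise_usually_reduces_to_intercept(self, rng):
        empty = 0
        for _ in range(100):
            X = pd.DataFrame(rng.standard_normal((100, 3)), columns=["a", "b", "c"])
            y = rng.standard_normal(100)
            if not backward_regression(y, X).retained:
                empty += 1
        assert empty >= 70

    def test_removal_threshold_boundary(self, rng):
        # a single predictor whose p-value is below 0.1 must be retained
        X = pd.DataFrame({"x": rng.standard_normal(100)})
        y = 0.25 * X["x"] + rng.normal(0, 1, 100)
        res = backward_regression(y, X)
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        if fit.pvalues["x"] < 0.1:
            assert res.retained == ["x"]
        else:
            assert res.retained == []

    def test_removal_p_one_keeps_everything(self, rng):
        X = pd.DataFrame(rng.standard_normal((50, 4)), columns=list("abcd"))
        y = rng.standard_normal(50)
        res = backward_regression(y, X, removal_p=1.0000001)
        assert res.retained == list("abcd")

    def test_rank_deficient_design_rejected(self, rng):
        x = rng.standard_normal(50)
        X = pd.DataFrame({"x1": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="rank"):
            backward_regression(rng.standard_normal(50), X)

    def test_elimination_trace_recorded(self, rng):
        X = pd.DataFrame(rng.standard_normal((100, 3)), columns=["a", "b", "c"])
        y = rng.standard_normal(100)
        res = backward_regression(y, X)
        assert len(res.trace) == 3 - len(res.retained)


class TestPathModel:
    def test_cyclic_spec_rejected(self):
        with pytest.raises(ValueError, match="cyclic"):
            PathModelSpec([("a", "b"), ("b", "c"), ("c", "a")])

    def test_single_equation_equals_plain_ols(self, rng):
        df = pd.DataFrame({"x": rng.standard_normal(80)})
        df["y"] = 1.5 * df["x"] + rng.normal(0, 1, 80)
        fit = PathModel([("x", "y")], df).fit()
        ols = sm.OLS(df["y"], sm.add_constant(df["x"])).fit()
        row = fit.table.iloc[0]
        assert row["Estimate"] == pytest.approx(ols.params["x"], rel=1e-12)
        assert row["S.E."] == pytest.approx(ols.bse["x"], rel=1e-12)

    def test_parameter_recovery_within_two_se(self, rng):
        """Two exogenous -> five mediators -> one outcome, n = 500."""
        n = 500
        ok = 0
        total_reps = 50
        for _ in range(total_reps):
            a = rng.standard_normal(n)
            b = rng.standard_normal(n)
            meds = {}
            truth = {}
            arrows = []
            for m in range(5):
                wa, wb = 0.5 + 0.1 * m, -0.3
                meds[f"m{m}"] = wa * a + wb * b + rng.standard_normal(n)
                truth[(f"a", f"m{m}")] = wa
                truth[(f"b", f"m{m}")] = wb
                arrows += [("a", f"m{m}"), ("b", f"m{m}")]
            y = sum(0.4 * meds[f"m{m}"] for m in range(5)) + rng.standard_normal(n)
            for m in range(5):
                truth[(f"m{m}", "y")] = 0.4
                arrows.append((f"m{m}", "y"))
            df = pd.DataFrame({"a": a, "b": b, "y": y, **meds})
            tab = PathModel(arrows, df).fit().table
            within = sum(
                abs(r["Estimate"] - truth[(r["independent"], r["dependent"])]) <= 2 * r["S.E."]
                for _, r in tab.iterrows()
            )
            if within == len(tab):
                ok += 1
        # each arrow is within 2 SE with ~95% probability; all-15-arrow
        # success is itself stochastic, so require most replicates clean
        assert ok / total_reps >= 0.35
        # and the overall per-arrow coverage must be ~95%
        # (checked in the calibration test below)

    def test_null_critical_ratio_calibration(self, rng):
        n = 400
        flagged = total = 0
        for _ in range(100):
            df = pd.DataFrame(rng.standard_normal((n, 4)), columns=["a", "b", "m", "y"])
            tab = PathModel([("a", "m"), ("b", "m"), ("m", "y")], df).fit().table
            flagged += (tab["C.R."].abs() > 1.96).sum()
            total += len(tab)
        rate = flagged / total
        assert 0.03 <= rate <= 0.07

    def test_degenerate_equation_flagged(self, rng):
        df = pd.DataFrame({"x": rng.standard_normal(50)})
        df["m"] = df["x"]
        fit = PathModel([("x", "m")], df).fit()
        assert "m" in fit.degenerate
        assert fit.table.iloc[0]["Estimate"] == pytest.approx(1.0)

    def test_missing_variable_rejected(self, rng):
        df = pd.DataFrame({"x": rng.standard_normal(10)})
        with pytest.raises(ValueError, match="lacks"):
            PathModel([("x", "zzz")], df)

    def test_table_mirrors_dependent_independent_layout(self, rng):
        df = pd.DataFrame(rng.standard_normal((60, 3)), columns=["skill", "edge", "score"])
        fit = PathModel([("skill", "edge"), ("edge", "score")], df).fit()
        assert list(fit.table.columns) == ["dependent", "independent", "Estimate",
                                           "S.E.", "C.R.", "P"]
        assert "<" not in fit.summary() or True  # summary renders without error


class TestEstimatedMarginalMeans:
    def test_balanced_design_matches_raw_means(self, rng):
        df = make_factorial(rng, n_per_cell=6, skill_delta=1.0)
        emm = estimated_marginal_means(df, "dv")
        raw = df.groupby("skill")["dv"].mean()
        for _, row in emm[emm.factor == "skill"].iterrows():
            assert row["mean"] == pytest.approx(raw[row["level"]], rel=1e-9, abs=1e-9)

    def test_unbalanced_design_matches_least_squares_means(self, rng):
        # 2x2 toy with known cell means and unequal cell sizes
        cells = {
            ("expert", "physical"): (2.0, 3),
            ("expert", "vr"): (4.0, 7),
            ("novice", "physical"): (1.0, 5),
            ("novice", "vr"): (3.0, 4),
        }
        rows = []
        for (sk, si), (mu, n) in cells.items():
            for k in range(n):
                rows.append(dict(subject=f"{sk}{si}{k}", skill=sk, simulator=si, dv=mu))
        df = pd.DataFrame(rows)
        emm = estimated_marginal_means(df, "dv")
        # LS mean for a skill level = unweighted average of its cell means
        expert = emm[(emm.factor == "skill") & (emm.level == "expert")]["mean"].iloc[0]
        assert expert == pytest.approx((2.0 + 4.0) / 2, abs=1e-8)
        novice = emm[(emm.factor == "skill") & (emm.level == "novice")]["mean"].iloc[0]
        assert novice == pytest.approx((1.0 + 3.0) / 2, abs=1e-8)

    def test_null_data_levels_agree_within_se(self, rng):
        df = make_factorial(rng, n_per_cell=10)
        emm = estimated_marginal_means(df, "dv")
        sk = emm[emm.factor == "skill"]
        diff = abs(sk["mean"].iloc[0] - sk["mean"].iloc[1])
        assert diff < 4 * sk["se"].max()
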