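"""Outcome-model tests: weighted logistic, weighted mixed slopes, suites."""
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from glycovar.config import BalanceSpec, ModelConfig
from glycovar.errors import ModelError
from glycovar.models import (
    fit_weighted_logistic,
    fit_weighted_mixed_slopes,
    sensitivity_suite,
    subgroup_suite,
)


def newton_weighted_logistic(X, y, w, tol=1e-12, max_iter=100):
    """Independent Newton-Raphson maximiser of the weighted Bernoulli loglik."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1 / (1 + np.exp(-eta))
        grad = X.T @ (w * (y - mu))
        H = (X * (w * mu * (1 - mu))[:, None]).T @ X
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


class TestWeightedLogistic:
    def test_saturated_2x2_is_cross_product_ratio(self):
        # counts (a,b; c,d) = (30,70; 50,50) -> OR = (50*70)/(50*30) = 7/3
        y = np.array([1] * 30 + [0] * 70 + [1] * 50 + [0] * 50)
        cats = np.array([1] * 100 + [5] * 100)
        w = np.ones(200)
        est = fit_weighted_logistic(y, cats, w)
        assert len(est) == 1
        assert est[0].term == "category_5_vs_1"
        assert est[0].estimate == pytest.approx(7 / 3, rel=1e-8)

    def test_matches_independent_newton_oracle(self):
        # 10-row weighted dataset; coefficients to 1e-8
        y = np.array([1, 0, 0, 1, 0, 1, 1, 0, 0, 1], float)
        cats = np.array([1, 1, 1, 2, 2, 2, 5, 5, 5, 5])
        w = np.array([0.5, 1.5, 2.0, 0.7, 1.3, 1.0, 2.5, 0.4, 1.1, 0.9])
        est = fit_weighted_logistic(y, cats, w)
        X = np.column_stack(
            [np.ones(10), (cats == 2).astype(float), (cats == 5).astype(float)]
        )
        beta = newton_weighted_logistic(X, y, w)
        assert np.log(est[0].estimate) == pytest.approx(beta[1], abs=1e-8)
        assert np.log(est[1].estimate) == pytest.approx(beta[2], abs=1e-8)

    def test_equal_weights_match_unweighted_logit(self):
        rng = np.random.default_rng(0)
        cats = rng.integers(1, 6, 400)
        y = rng.random(400) < 0.3
        est = fit_weighted_logistic(y, cats, np.ones(400))
        X = np.column_stack(
            [np.ones(400)] + [(cats == g).astype(float) for g in (2, 3, 4, 5)]
        )
        ref = sm.Logit(y.astype(float), X).fit(disp=0)
        for j, e in enumerate(est, start=1):
            assert np.log(e.estimate) == pytest.approx(ref.params[j], abs=1e-6)

    def test_null_recovery(self):
        rng = np.random.default_rng(1)
        cats = rng.integers(1, 6, 5000)
        y = rng.random(5000) < 0.2
        est = fit_weighted_logistic(y, cats, np.ones(5000))
        for e in est:
            assert abs(e.estimate - 1.0) < 0.25  # ~3 MC sds
            assert e.ci_low < 1.0 < e.ci_high

    def test_single_class_category_raises(self):
        y = np.array([1, 1, 1, 0, 1, 0])
        cats = np.array([1, 1, 1, 2, 2, 2])
        with pytest.raises(ModelError, match="category 1"):
            fit_weighted_logistic(y, cats, np.ones(6))

    def test_missing_reference_raises(self):
        with pytest.raises(ModelError, match="reference"):
            fit_weighted_logistic(
                np.array([1, 0, 1, 0]), np.array([2, 2, 3, 3]), np.ones(4)
            )

    def test_nonpositive_weights_raise(self):
        with pytest.raises(ModelError, match="weights"):
            fit_weighted_logistic(
                np.array([1, 0, 1, 0]), np.array([1, 1, 2, 2]), np.array([1, 1, 0, 1])
            )

    def test_sandwich_wider_than_model_se_under_weighting(self):
        rng = np.random.default_rng(5)
        cats = rng.integers(1, 6, 2000)
        y = rng.random(2000) < 0.25
        w = rng.uniform(0.2, 3.0, 2000)
        robust = fit_weighted_logistic(y, cats, w, ModelConfig())
        model = fit_weighted_logistic(
            y, cats, w, ModelConfig(logistic_variance="model")
        )
        # not a theorem, but with variable weights the sandwich should differ
        assert any(
            abs(r.se - m.se) / m.se > 0.02 for r, m in zip(robust, model)
        )


def make_long(slopes_by_cat, n_per_cat=30, n_obs=5, noise=0.0, re_sd=(0.0, 0.0), seed=0):
    """Long eGFR table with planted per-category slopes."""
    rng = np.random.default_rng(seed)
    rows = []
    cats = {}
    sid = 0
    for g, s in slopes_by_cat.items():
        for _ in range(n_per_cat):
            sid += 1
            name = f"P{sid:04d}"
            cats[name] = g
            a = 90 + rng.normal(0, re_sd[0])
            b = s + rng.normal(0, re_sd[1])
            t = np.linspace(0, 4, n_obs)
            y = a + b * t + rng.normal(0, noise, n_obs)
            rows.extend((name, ti, yi) for ti, yi in zip(t, y))
    long = pd.DataFrame(rows, columns=["subject_id", "time_years", "egfr"])
    return long, pd.Series(cats)


class TestWeightedMixedSlopes:
    def test_noise_free_exactness(self):
        slopes = {1: -0.4, 2: -0.9, 4: -2.0}
        long, cats = make_long(slopes, n_per_cat=8, noise=0.0)
        w = pd.Series(1.0, index=cats.index)
        fit = fit_weighted_mixed_slopes(long, cats, w)
        assert fit.reference_slope.estimate == pytest.approx(-0.4, abs=1e-6)
        diffs = {e.term: e.estimate for e in fit.differences}
        assert diffs["category_2_x_time"] == pytest.approx(-0.5, abs=1e-6)
        assert diffs["category_4_x_time"] == pytest.approx(-1.6, abs=1e-6)
        assert fit.sigma2 < 1e-6

    def test_exceeds_mid_flag(self):
        slopes = {1: -0.4, 2: -0.9, 4: -2.0}
        long, cats = make_long(slopes, n_per_cat=8)
        fit = fit_weighted_mixed_slopes(long, cats, pd.Series(1.0, index=cats.index))
        flags = {e.term: e.exceeds_mid for e in fit.differences}
        assert flags["category_2_x_time"] is False  # |−0.5| < 0.75
        assert flags["category_4_x_time"] is True  # |−1.6| > 0.75

    def test_matches_statsmodels_mixedlm_with_unit_weights(self):
        slopes = {1: -0.5, 3: -1.2}
        long, cats = make_long(
            slopes, n_per_cat=25, n_obs=6, noise=2.0, re_sd=(8.0, 0.8), seed=3
        )
        w = pd.Series(1.0, index=cats.index)
        fit = fit_weighted_mixed_slopes(long, cats, w)

        df = long.copy()
        df["cat3"] = (df["subject_id"].map(cats) == 3).astype(float)
        df["t"] = df["time_years"]
        df["cat3_t"] = df["cat3"] * df["t"]
        X = sm.add_constant(df[["cat3", "t", "cat3_t"]])
        md = sm.MixedLM(
            df["egfr"], X, groups=df["subject_id"], exog_re=sm.add_constant(df[["t"]])
        )
        ref = md.fit(reml=False, method="lbfgs", maxiter=500)
        assert fit.reference_slope.estimate == pytest.approx(ref.params["t"], abs=1e-3)
        assert fit.differences[0].estimate == pytest.approx(
            ref.params["cat3_t"], abs=1e-3
        )
        assert fit.sigma2 == pytest.approx(ref.scale, rel=1e-2)
        assert fit.reference_slope.se == pytest.approx(ref.bse["t"], rel=2e-2)

    def test_integer_weights_equal_replication(self):
        # weight 2 on a subject == duplicating that subject with weight 1:
        # an independent route to validate the weighted likelihood
        slopes = {1: -0.5, 2: -1.5}
        long, cats = make_long(
            slopes, n_per_cat=12, n_obs=5, noise=3.0, re_sd=(6.0, 0.7), seed=9
        )
        rng = np.random.default_rng(4)
        w = pd.Series(rng.integers(1, 3, len(cats)).astype(float), index=cats.index)
        fit_w = fit_weighted_mixed_slopes(long, cats, w)

        dup_long, dup_cats = [long], dict(cats)
        for name, wi in w.items():
            if wi == 2.0:
                block = long[long["subject_id"] == name].copy()
                block["subject_id"] = name + "_dup"
                dup_long.append(block)
                dup_cats[name + "_dup"] = cats[name]
        long2 = pd.concat(dup_long, ignore_index=True)
        cats2 = pd.Series(dup_cats)
        fit_r = fit_weighted_mixed_slopes(
            long2, cats2, pd.Series(1.0, index=cats2.index)
        )
        assert fit_w.reference_slope.estimate == pytest.approx(
            fit_r.reference_slope.estimate, abs=1e-5
        )
        assert fit_w.differences[0].estimate == pytest.approx(
            fit_r.differences[0].estimate, abs=1e-5
        )
        assert fit_w.sigma2 == pytest.approx(fit_r.sigma2, rel=1e-4)

    def test_null_differences_near_zero(self):
        slopes = {g: -0.8 for g in range(1, 6)}
        long, cats = make_long(
            slopes, n_per_cat=60, n_obs=6, noise=3.0, re_sd=(8.0, 0.5), seed=6
        )
        fit = fit_weighted_mixed_slopes(long, cats, pd.Series(1.0, index=cats.index))
        for e in fit.differences:
            assert abs(e.estimate) < 0.3
            assert e.ci_low < 0 < e.ci_high

    def test_requires_three_measures(self):
        long = pd.DataFrame(
            {"subject_id": ["A", "A", "B", "B", "B"], "time_years": [0, 1, 0, 1, 2],
             "egfr": [90, 85, 88, 86, 84]}
        )
        cats = pd.Series({"A": 1, "B": 2})
        with pytest.raises(ModelError, match="<3"):
            fit_weighted_mixed_slopes(long, cats, pd.Series(1.0, index=cats.index))


def make_cohort_frame(n=600, seed=0, insulin_effect=0.0):
    """Synthetic analysis table + long eGFR with optional insulin x band effect."""
    rng = np.random.default_rng(seed)
    cats = rng.choice([1, 4], n)
    insulin = rng.random(n) < 0.5
    base_slope = np.where(cats == 1, -0.3, -1.0)
    slope = base_slope + insulin_effect * insulin * (cats == 4)
    slope = slope + rng.normal(0, 3.0, n)
    sid = np.array([f"Q{i:05d}" for i in range(n)])
    t = np.tile(np.linspace(0, 4, 6), n)
    y = (
        np.repeat(90 + rng.normal(0, 8, n), 6)
        + np.repeat(slope, 6) * t
        + rng.normal(0, 2.0, 6 * n)
    )
    long = pd.DataFrame(
        {"subject_id": np.repeat(sid, 6), "time_years": t, "egfr": y}
    )
    d0 = pd.Timestamp("2015-01-01")
    cohort = pd.DataFrame(
        {
            "subject_id": sid,
            "hvs_category": cats,
            "rapid_decliner": slope <= -5.0,
            "mean_slope": slope,
            "age_at_index": rng.normal(58 + 2 * (cats == 4), 9, n),
            "female": (rng.random(n) < 0.4).astype(int),
            "ever_insulin": insulin.astype(int),
            "baseline_egfr": rng.normal(90, 15, n),
            "twa_hba1c": rng.normal(7.2 + 0.4 * (cats == 4), 0.8, n),
            "baseline_hba1c": rng.normal(7.2 + 0.4 * (cats == 4), 0.9, n),
            "adherence": rng.uniform(1.0, 3.5, n),
            "ever_sglt2_glp1": (rng.random(n) < 0.06).astype(int),
            "last_hba1c_date": d0 + pd.to_timedelta(rng.integers(1400, 1500, n), "D"),
            "last_scr_date": d0 + pd.to_timedelta(rng.integers(1400, 1500, n), "D"),
        }
    )
    cohort["baseline_egfr_lt60"] = (cohort["baseline_egfr"] < 60).astype(int)
    cohort["htn_or_ascvd"] = (rng.random(n) < 0.6).astype(int)
    cohort["ever_statin"] = (rng.random(n) < 0.6).astype(int)
    cohort["ever_arb_acei"] = (rng.random(n) < 0.4).astype(int)
    return cohort, long


SMALL_SPEC = BalanceSpec(covariates=("age_at_index", "female", "twa_hba1c"))


class TestSubgroupSuite:
    def test_strata_partition_cohort(self):
        cohort, long = make_cohort_frame(seed=2)
        out = subgroup_suite(cohort, long, SMALL_SPEC)
        for name in ("sex", "age", "insulin", "baseline_egfr"):
            sizes = [
                v["n"] if "n" in v else 0
                for k, v in out.items()
                if k[0] == name and "skipped" not in v
            ]
            skipped = [
                k for k, v in out.items() if k[0] == name and "skipped" in v
            ]
            if not skipped:
                assert sum(sizes) == len(cohort), name

    def test_insulin_modifies_slope_difference(self):
        cohort, long = make_cohort_frame(n=1200, seed=7, insulin_effect=-1.5)
        out = subgroup_suite(cohort, long, SMALL_SPEC)
        ins = out[("insulin", "insulin")]
        no_ins = out[("insulin", "no_insulin")]
        assert "skipped" not in ins and "skipped" not in no_ins
        d_ins = ins["mixed"].differences[0].estimate
        d_no = no_ins["mixed"].differences[0].estimate
        assert d_ins < d_no - 0.5  # planted extra decline among insulin users

    def test_small_stratum_skipped(self):
        cohort, long = make_cohort_frame(n=300, seed=1)
        cohort["ever_insulin"] = 0
        cohort.loc[cohort.index[:5], "ever_insulin"] = 1
        out = subgroup_suite(cohort, long, SMALL_SPEC)
        assert "skipped" in out[("insulin", "insulin")]


class TestSensitivitySuite:
    def test_wide_window_reproduces_full_estimates(self):
        cohort, long = make_cohort_frame(seed=3)
        out = sensitivity_suite(
            cohort, long, SMALL_SPEC, scenarios=("window_5y",)
        )
        full = sensitivity_suite(
            cohort, long, SMALL_SPEC, scenarios=("exclude_sglt2_glp1",)
        )
        # window 5y covers every measurement (max t = 4): same data as the
        # full analysis; compare against a direct fit on the whole cohort
        from glycovar.balancing import entropy_balance

        bal = entropy_balance(cohort, cohort["hvs_category"].to_numpy(), SMALL_SPEC)
        direct = fit_weighted_mixed_slopes(
            long,
            pd.Series(cohort["hvs_category"].to_numpy(), index=cohort["subject_id"]),
            pd.Series(bal.weights, index=cohort["subject_id"]),
        )
        win = out["window_5y"]
        assert win["dropped"] == 0
        assert win["mixed"].differences[0].estimate == pytest.approx(
            direct.differences[0].estimate, abs=1e-9
        )

    def test_windowed_slope_changes_rapid_flags(self):
        cohort, long = make_cohort_frame(seed=8)
        out = sensitivity_suite(cohort, long, SMALL_SPEC, scenarios=("window_2y",))
        assert "infeasible" not in out["window_2y"]
        assert out["window_2y"]["n"] == len(cohort)

    def test_unparallel_exclusion(self):
        cohort, long = make_cohort_frame(seed=4)
        cohort = cohort.copy()
        # make exactly one subject's last HbA1c and creatinine 91 days apart
        cohort.loc[cohort.index[0], "last_scr_date"] = (
            cohort.loc[cohort.index[0], "last_hba1c_date"] + pd.Timedelta(days=91)
        )
        cohort.loc[cohort.index[1:], "last_scr_date"] = cohort.loc[
            cohort.index[1:], "last_hba1c_date"
        ]
        out = sensitivity_suite(cohort, long, SMALL_SPEC, scenarios=("unparallel_90d",))
        assert out["unparallel_90d"]["dropped"] == 1

    def test_baseline_hba1c_weights_variant(self):
        cohort, long = make_cohort_frame(seed=5)
        out = sensitivity_suite(
            cohort, long, SMALL_SPEC,
            scenarios=("baseline_hba1c_weights", "exclude_egfr_lt30"),
        )
        assert "infeasible" not in out["baseline_hba1c_weights"]
        # recovered slope difference stays near the planted truth (-0.7)
        d = out["baseline_hba1c_weights"]["mixed"].differences[0].estimate
        assert d == pytest.approx(-0.7, abs=0.45)

    def test_scenario_leaving_category_empty_is_infeasible(self):
        cohort, long = make_cohort_frame(seed=6)
        cohort = cohort.copy()
        # every band-4 subject is an SGLT2i/GLP-1RA user -> exclusion empties it
        cohort["ever_sglt2_glp1"] = (cohort["hvs_category"] == 4).astype(int)
        out = sensitivity_suite(cohort, long, SMALL_SPEC, scenarios=("exclude_sglt2_glp1",))
        assert "infeasible" in out["exclude_sglt2_glp1"]
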