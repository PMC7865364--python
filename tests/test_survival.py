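"""Kaplan-Meier, log-rank, stratified Cox, RMST, chi2 shares, event sizing."""

import numpy as np
import pandas as pd
import pytest

from immunoscore import (
    ValidationError,
    chi2_importance,
    cox_fit,
    km_fit,
    logrank_test,
    rmst_compare,
    schoenfeld_sample_size,
)
from immunoscore.survival import _rmst_single


# --- Kaplan-Meier -----------------------------------------------------------


def test_km_no_events_flat_curve():
    est = km_fit([5.0, 8.0, 12.0], [0, 0, 0])
    assert (est.table["survival"] == 1.0).all()
    assert np.isinf(est.median)


def test_km_hand_worked_six_subjects():
    """times 1, 2+, 3, 4+, 5, 6 (+ censored): S = 5/6, 5/8, 5/16, 0."""
    est = km_fit([1, 2, 3, 4, 5, 6], [1, 0, 1, 0, 1, 1])
    s = est.table.set_index("time")["survival"]
    assert s.loc[1.0] == pytest.approx(5 / 6)
    assert s.loc[3.0] == pytest.approx(5 / 6 * 3 / 4)
    assert s.loc[5.0] == pytest.approx(5 / 6 * 3 / 4 * 1 / 2)
    assert s.loc[6.0] == 0.0


def test_km_matches_empirical_survival_without_censoring(rng):
    t = rng.exponential(10, 300)
    est = km_fit(t, np.ones(300))
    for q in (5.0, 10.0, 20.0):
        emp = (t > q).mean()
        row = est.table[est.table["time"] <= q]
        assert row["survival"].iloc[-1] == pytest.approx(emp, abs=1e-12)


def test_km_exponential_closed_form():
    rng = np.random.default_rng(3)
    t = rng.exponential(50.0, 2000)
    est = km_fit(t, np.ones(2000), horizons=(60.0,))
    s60, lo, hi = est.rates[60.0]
    se = np.sqrt(est.table[est.table["time"] <= 60.0]["greenwood_var"].iloc[-1])
    assert abs(s60 - np.exp(-1.2)) < 3 * se
    assert lo < s60 < hi


def test_km_greenwood_and_ci_sane(rng):
    t = rng.exponential(30, 200)
    e = (rng.uniform(size=200) < 0.7).astype(int)
    est = km_fit(t[e >= 0], e)
    tab = est.table
    assert (np.diff(tab["survival"]) <= 1e-12).all()
    assert ((tab["ci_low"] >= 0) & (tab["ci_high"] <= 1)).all()
    assert (tab["ci_low"] <= tab["survival"] + 1e-12).all()


def test_km_all_zero_times_errors():
    with pytest.raises(ValidationError):
        km_fit([0.0, 0.0], [1, 1])


# --- log-rank ---------------------------------------------------------------


def test_logrank_single_group_errors():
    with pytest.raises(ValidationError):
        logrank_test([1.0, 2.0], [1, 1], ["a", "a"])


def test_logrank_extreme_separation():
    t = np.r_[np.ones(50), np.full(50, 2.0)]
    e = np.r_[np.ones(50), np.zeros(50)]
    g = np.r_[["a"] * 50, ["b"] * 50]
    res = logrank_test(t, e, g)
    assert np.isfinite(res.statistic)
    assert res.p_value < 0.05


def test_logrank_power_under_strong_hazard_ratio():
    rng = np.random.default_rng(8)
    hits = 0
    for _ in range(20):
        t = np.r_[rng.exponential(30, 200), rng.exponential(10, 200)]
        g = np.r_[np.zeros(200), np.ones(200)]
        if logrank_test(t, np.ones(400), g).p_value < 0.001:
            hits += 1
    assert hits == 20


def test_logrank_agrees_with_cox_wald_asymptotically():
    rng = np.random.default_rng(4)
    n = 2000
    g = rng.integers(0, 2, n)
    t = rng.exponential(np.where(g == 1, 20, 26))
    e = np.ones(n)
    lr = logrank_test(t, e, g)
    df = pd.DataFrame({"t": t, "e": e, "g": g.astype(float)})
    fit = cox_fit(df, "t", "e", ["g"], strata=None)
    row = fit.summary.iloc[0]
    wald = (row.coef / row.se) ** 2
    assert lr.statistic == pytest.approx(wald, rel=0.10)


# --- Cox --------------------------------------------------------------------


def test_cox_constant_covariate_degenerate(default_cohort_frame):
    df = default_cohort_frame.copy()
    df["flat"] = "same"
    fit = cox_fit(df, "ttr_months", "ttr_event", ["flat"], strata="center")
    row = fit.summary.iloc[0]
    assert row.flag == "degenerate" and row.hr == 1.0 and row.p == 1.0


def test_cox_recovers_hazard_ratio_two():
    rng = np.random.default_rng(12)
    n = 1000
    g = rng.integers(0, 2, n)
    t = rng.exponential(np.where(g == 1, 15.0, 30.0))
    c = rng.uniform(0, 60, n)
    df = pd.DataFrame(
        {"t": np.minimum(t, c), "e": (t <= c).astype(int), "g": np.where(g == 1, "B", "A"),
         "center": rng.choice(["c1", "c2", "c3"], n)}
    )
    fit = cox_fit(df, "t", "e", ["g"], strata="center")
    row = fit.summary.iloc[0]
    assert abs(row.coef - np.log(2.0)) < 2 * row.se
    assert fit.c_index > 0.5


def test_cox_separation_flagged():
    # one level with zero events separates completely
    df = pd.DataFrame(
        {
            "t": np.r_[np.arange(1.0, 21.0), np.arange(30.0, 50.0)],
            "e": np.r_[np.ones(20), np.zeros(20)],
            "g": ["bad"] * 20 + ["good"] * 20,
        }
    )
    fit = cox_fit(df, "t", "e", ["g"], strata=None)
    row = fit.summary.iloc[0]
    assert row.flag == "separated"
    assert row.hr == 0.0 and row.ci_high == np.inf


def test_cox_stratified_invariant_to_strata_relabel(default_cohort_frame):
    df = default_cohort_frame.copy()
    fit1 = cox_fit(df, "ttr_months", "ttr_event", ["n_stage"], strata="center",
                   ref_levels={"n_stage": "N0"})
    relabel = {c: f"site-{i}" for i, c in enumerate(df["center"].unique())}
    df["center"] = df["center"].map(relabel)
    fit2 = cox_fit(df, "ttr_months", "ttr_event", ["n_stage"], strata="center",
                   ref_levels={"n_stage": "N0"})
    pd.testing.assert_frame_equal(fit1.summary, fit2.summary)


def test_c_index_perfect_and_null(rng):
    n = 400
    risk = rng.normal(size=n)
    t = np.argsort(np.argsort(-risk)).astype(float) + 1.0  # lower risk -> longer time, no ties
    df = pd.DataFrame({"t": t, "e": np.ones(n), "x": risk})
    fit = cox_fit(df, "t", "e", ["x"], strata=None)
    assert fit.c_index == pytest.approx(1.0)
    df["x"] = rng.normal(size=n)  # independent predictor
    fit0 = cox_fit(df, "t", "e", ["x"], strata=None)
    assert 0.45 < fit0.c_index < 0.55


# --- chi2 importance --------------------------------------------------------


def test_chi2_share_single_covariate(default_cohort_frame):
    fit = cox_fit(default_cohort_frame, "ttr_months", "ttr_event", ["n_stage"],
                  strata="center", ref_levels={"n_stage": "N0"})
    shares = chi2_importance(fit)
    assert shares == {"n_stage": pytest.approx(1.0)}


def test_chi2_shares_symmetric_for_equal_effects():
    rng = np.random.default_rng(21)
    n = 2000
    x1 = rng.integers(0, 2, n)
    x2 = rng.integers(0, 2, n)
    lam = 0.03 * np.exp(0.7 * x1 + 0.7 * x2)
    t = rng.exponential(1 / lam)
    df = pd.DataFrame({"t": t, "e": np.ones(n), "x1": x1.astype(float), "x2": x2.astype(float)})
    fit = cox_fit(df, "t", "e", ["x1", "x2"], strata=None)
    shares = chi2_importance(fit)
    assert sum(shares.values()) == pytest.approx(1.0)
    assert 0.35 < shares["x1"] < 0.65


# --- RMST -------------------------------------------------------------------


def test_rmst_identical_arms():
    t = np.array([3.0, 6.0, 9.0, 12.0] * 2)
    e = np.ones(8)
    g = np.r_[np.zeros(4), np.ones(4)]
    res = rmst_compare(t, e, g)
    assert res.difference == 0.0
    assert res.p_value == 1.0


def test_rmst_exponential_closed_form():
    rng = np.random.default_rng(6)
    t = rng.exponential(50.0, 2000)
    r, v = _rmst_single(t, np.ones(2000), 60.0)
    truth = (1 - np.exp(-0.02 * 60)) / 0.02
    assert abs(r - truth) < 3 * np.sqrt(v)


def test_rmst_matches_lifelines_point_estimate(rng):
    from lifelines import KaplanMeierFitter
    from lifelines.utils import restricted_mean_survival_time

    t = rng.exponential(25, 300)
    e = (rng.uniform(size=300) < 0.8).astype(float)
    tau = 40.0
    r, _ = _rmst_single(t, e, tau)
    kmf = KaplanMeierFitter().fit(t, e)
    assert r == pytest.approx(restricted_mean_survival_time(kmf, t=tau), rel=1e-9)


def test_rmst_difference_sign_follows_km_dominance(rng):
    t = np.r_[rng.exponential(40, 400), rng.exponential(15, 400)]
    e = np.ones(800)
    g = np.r_[["slow"] * 400, ["fast"] * 400]
    res = rmst_compare(t, e, g, tau=30.0)
    # sorted labels: ("fast", "slow"); slow arm dominates -> positive difference
    assert res.groups == ("fast", "slow")
    assert res.difference > 0
    assert res.p_value < 0.01
    assert res.ci[0] < res.difference < res.ci[1]
    assert all(0 <= v <= 30.0 for v in res.rmst.values())


def test_rmst_coverage_of_configured_gap():
    """The 95% CI of the RMST difference covers the true gap in most seeds."""
    lam0, lam1, tau = 1 / 40.0, 1 / 15.0, 30.0
    truth = (1 - np.exp(-lam0 * tau)) / lam0 - (1 - np.exp(-lam1 * tau)) / lam1
    cover = 0
    n_rep = 50
    for s in range(n_rep):
        rng = np.random.default_rng(300 + s)
        t = np.r_[rng.exponential(1 / lam0, 250), rng.exponential(1 / lam1, 250)]
        g = np.r_[np.ones(250), np.zeros(250)]  # sorted labels: 0.0 then 1.0
        res = rmst_compare(t, np.ones(500), g, tau=tau)
        if res.ci[0] <= truth <= res.ci[1]:
            cover += 1
    assert cover >= 44  # ~95% nominal; allows Monte-Carlo slack


def test_rmst_tau_beyond_followup_errors():
    with pytest.raises(ValidationError, match="tau"):
        rmst_compare([5.0, 6.0, 7.0, 8.0], [1, 1, 1, 1], [0, 0, 1, 1], tau=100.0)


# --- Schoenfeld sizing ------------------------------------------------------


def test_schoenfeld_reference_case():
    """HR 2, two-sided 5% alpha, 80% power, 1:1 allocation -> 66 events."""
    out = schoenfeld_sample_size(2.0, alpha=0.05, sided=2, power=0.8, allocation=0.5)
    assert out["events"] == 66
    assert out["total_n"] == 66


def test_schoenfeld_event_fraction_and_sides():
    one_sided = schoenfeld_sample_size(2.1, alpha=0.05, sided=1, power=0.9,
                                       allocation=0.5, event_fraction=0.6)
    assert one_sided["total_n"] == pytest.approx(104, abs=1)
    two_sided = schoenfeld_sample_size(2.1, alpha=0.05, sided=2, power=0.9,
                                       allocation=0.5, event_fraction=0.6)
    assert two_sided["raw_events"] > one_sided["raw_events"]


def test_schoenfeld_diverges_near_null():
    e = [schoenfeld_sample_size(hr)["raw_events"] for hr in (1.5, 1.1, 1.01)]
    assert e[0] < e[1] < e[2]
    with pytest.raises(ValidationError):
        schoenfeld_sample_size(1.0)


def test_schoenfeld_log_hr_scaling_identity():
    """Doubling ln(hr)^2 halves the required events exactly."""
    a = schoenfeld_sample_size(2.0)["raw_events"]
    b = schoenfeld_sample_size(float(np.exp(np.sqrt(2) * np.log(2.0))))["raw_events"]
    assert a / b == pytest.approx(2.0, rel=1e-9)
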