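"""Percentile conversion, category assignment, and optimal cut-off search."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunoscore import (
    CutoffModel,
    DensityQuartet,
    ImmunoscoreScorer,
    PercentileReference,
    ValidationError,
    assign_categories,
    empirical_percentile,
    mean_percentile,
)
from immunoscore.cohort import SyntheticSlide
from immunoscore.scoring import (
    DENSITY_COLUMNS,
    optimal_cutoff,
    optimal_cutoffs,
    quantify_density,
    two_group_logrank_thresholds,
)

UNIT_CUTS = CutoffModel(thresholds={c: 100.0 for c in DENSITY_COLUMNS})


def _quartet(cd3_ct, cd8_ct, cd3_im=None, cd8_im=None):
    return DensityQuartet(cd3_ct, cd8_ct, cd3_im, cd8_im)


# --- density quantification -----------------------------------------------


def test_counting_oracle():
    """200 points placed inside a 2 mm^2 tumor-center mask quantify to
    exactly 100 cells/mm^2."""
    w = np.sqrt(2.0)
    rng = np.random.default_rng(0)
    pts = np.column_stack([rng.uniform(0, w, 200), rng.uniform(0, w, 200)])
    slide = SyntheticSlide(masks={"ct": (0.0, 0.0, w, w)}, points={"cd3": pts, "cd8": np.empty((0, 2))}, im_present=False)
    assert quantify_density(slide, "cd3", "ct") == pytest.approx(100.0)
    assert quantify_density(slide, "cd8", "ct") == 0.0
    assert quantify_density(slide, "cd3", "im") is None


# --- percentiles -----------------------------------------------------------


def test_midrank_percentile_examples():
    assert empirical_percentile(2.0, [1.0, 2.0, 3.0]) == pytest.approx(50.0)
    n = 7
    ref = np.arange(1.0, n + 1)
    # strictly below every reference value -> 0; at the minimum -> 50/n
    assert empirical_percentile(0.0, ref) == 0.0
    assert empirical_percentile(1.0, ref) == pytest.approx(50.0 / n)
    assert empirical_percentile(100.0, ref) == 100.0


def test_percentiles_increase_with_rank(rng):
    ref = rng.normal(size=100)
    distinct = np.unique(ref)
    pcts = [empirical_percentile(x, ref) for x in distinct]
    assert np.all(np.diff(pcts) > 0)


def test_percentile_empty_reference_errors():
    with pytest.raises(ValidationError):
        empirical_percentile(1.0, [])


@given(st.floats(1.0, 1e4), st.floats(1.0, 1e4), st.floats(1.0, 1e4), st.floats(1.0, 1e4))
@settings(max_examples=50, derandomize=True)
def test_mean_percentile_permutation_invariance(a, b, c, d):
    base = {"cd3_ct": a, "cd8_ct": b, "cd3_im": c, "cd8_im": d}
    perm = {"cd3_ct": d, "cd8_ct": c, "cd3_im": b, "cd8_im": a}
    assert mean_percentile(base) == pytest.approx(np.mean([a, b, c, d]))
    assert mean_percentile(base) == pytest.approx(mean_percentile(perm))


def test_mean_percentile_ct_only():
    assert mean_percentile({"cd3_ct": 60.0, "cd8_ct": 80.0}) == pytest.approx(70.0)
    assert mean_percentile({"cd3_ct": 10.0, "cd8_ct": 20.0, "cd3_im": 30.0, "cd8_im": 40.0}) == 25.0
    with pytest.raises(ValidationError):
        mean_percentile({"cd3_ct": 60.0})


# --- category assignment ---------------------------------------------------


@pytest.mark.parametrize(
    "quartet, is_cat, isb_cat, is3",
    [
        (_quartet(10, 10, 10, 10), 0, 0, "IS-0"),      # all low
        (_quartet(500, 500, 500, 500), 4, 2, "IS-3-4"),  # all high
        (_quartet(500, 500, 10, 10), 2, 2, "IS-1-2"),  # CT high, IM low
        (_quartet(500, 10, 10, 10), 1, 1, "IS-1-2"),
        (_quartet(100, 100, 100, 100), 4, 2, "IS-3-4"),  # high call closed at threshold
        (_quartet(500, 500), None, 2, None),           # IM missing -> unclassified IS
    ],
)
def test_assign_categories(quartet, is_cat, isb_cat, is3):
    r = assign_categories(quartet, UNIT_CUTS)
    assert r.is_category == is_cat
    assert r.isb_category == isb_cat
    assert r.is3_group == is3


@given(
    st.floats(1.0, 1e3), st.floats(1.0, 1e3), st.floats(1.0, 1e3), st.floats(1.0, 1e3),
    st.sampled_from(DENSITY_COLUMNS), st.floats(1.0, 500.0),
)
@settings(max_examples=100, derandomize=True)
def test_raising_one_density_never_lowers_scores(a, b, c, d, col, bump):
    """Monotonicity: increasing any single density cannot decrease IS or ISb."""
    vals = {"cd3_ct": a, "cd8_ct": b, "cd3_im": c, "cd8_im": d}
    r0 = assign_categories(DensityQuartet(**vals), UNIT_CUTS)
    vals[col] += bump
    r1 = assign_categories(DensityQuartet(**vals), UNIT_CUTS)
    assert r1.is_category >= r0.is_category
    assert r1.isb_category >= r0.isb_category


@given(st.floats(1.0, 1e3), st.floats(1.0, 1e3), st.floats(1.0, 1e3), st.floats(1.0, 1e3))
@settings(max_examples=50, derandomize=True)
def test_isb_at_least_one_when_is_high(a, b, c, d):
    """At most two of four highs can come from the IM, so IS >= 3 forces ISb >= 1."""
    r = assign_categories(DensityQuartet(a, b, c, d), UNIT_CUTS)
    if r.is_category >= 3:
        assert r.isb_category >= 1


def test_rank_invariance_under_monotone_transform(rng):
    """A strictly increasing transform of densities and thresholds together
    leaves percentiles and categories unchanged."""
    ref = rng.lognormal(5, 1, 60)
    x = float(np.quantile(ref, 0.3))
    assert empirical_percentile(x, ref) == pytest.approx(empirical_percentile(np.log(x), np.log(ref)))
    q = DensityQuartet(120.0, 80.0, 150.0, 90.0)
    r_raw = assign_categories(q, UNIT_CUTS)
    q_log = DensityQuartet(*(np.log(v) for v in (120.0, 80.0, 150.0, 90.0)))
    cuts_log = CutoffModel(thresholds={c: float(np.log(100.0)) for c in DENSITY_COLUMNS})
    r_log = assign_categories(q_log, cuts_log)
    assert (r_raw.is_category, r_raw.isb_category) == (r_log.is_category, r_log.isb_category)


# --- optimal cut-off search -------------------------------------------------


def test_vectorized_logrank_matches_lifelines(rng):
    from lifelines.statistics import logrank_test as ll_logrank

    values = rng.uniform(0, 1, 150)
    times = rng.exponential(20, 150)
    events = (rng.uniform(size=150) < 0.7).astype(float)
    grid = np.quantile(values, [0.2, 0.4, 0.6, 0.8])
    z = two_group_logrank_thresholds(values, times, events, grid)
    for g, zi in zip(grid, z):
        m = values >= g
        res = ll_logrank(times[m], times[~m], events[m], events[~m])
        assert zi**2 == pytest.approx(res.test_statistic, rel=1e-6)


def test_cutoff_degenerate_inputs():
    with pytest.raises(ValidationError, match="degenerate"):
        optimal_cutoff(np.ones(50), np.arange(50.0), np.ones(50))
    with pytest.raises(ValidationError):
        optimal_cutoff(np.arange(50.0), np.arange(50.0), np.zeros(50))  # no events


def test_cutoffs_require_min_events(default_cohort_frame):
    df = default_cohort_frame
    with pytest.raises(ValidationError, match="events"):
        optimal_cutoffs(df, df["ttr_months"], np.zeros(len(df)))


def test_cutoff_recovers_strong_changepoint():
    """A sharp hazard changepoint on a coarse density grid is recovered."""
    rng = np.random.default_rng(5)
    v = np.round(rng.uniform(0, 1, 400) * 20) / 20
    lam = np.where(v >= 0.5, 0.10, 0.02)
    t = rng.exponential(1 / lam)
    c = rng.uniform(0, 60, 400)
    thr, grid, z = optimal_cutoff(v, np.minimum(t, c), (t <= c).astype(float))
    assert abs(thr - 0.5) <= 0.05 + 1e-12
    assert grid.size == np.abs(z).size


def test_null_cutoff_statistic_within_permutation_envelope():
    """With no density-outcome association the maximally selected statistic
    rarely exceeds the 99th percentile of its permutation null."""
    rng = np.random.default_rng(11)
    exceed = 0
    n_seeds, n_perm = 15, 99
    for _ in range(n_seeds):
        v = rng.uniform(0, 1, 150)
        t = rng.exponential(25, 150)
        e = (rng.uniform(size=150) < 0.7).astype(float)
        _, grid, z = optimal_cutoff(v, t, e)
        obs = np.abs(z).max()
        null = []
        for _ in range(n_perm):
            vp = rng.permutation(v)
            _, _, zp = optimal_cutoff(vp, t, e)
            null.append(np.abs(zp).max())
        if obs > np.quantile(null, 0.99):
            exceed += 1
    assert exceed <= 3


# --- scorer (fit/transform) -------------------------------------------------


def test_scorer_fit_transform_all_levels(default_cohort_frame):
    """On the default synthetic cohort every IS level (0-4) and ISb level
    (0-2) occurs, and unclassified patients are exactly the IM-missing ones."""
    df = default_cohort_frame
    scorer = ImmunoscoreScorer()
    y = df[["ttr_months", "ttr_event"]].to_numpy(float)
    out = scorer.fit(df, y).transform(df)
    assert set(out["isb_category"]) == {0, 1, 2}
    assert set(out["is_category"].dropna()) == {0, 1, 2, 3, 4}
    assert out["is_category"].isna().equals(df["cd3_im"].isna())
    assert ((out["mean_percentile"] >= 0) & (out["mean_percentile"] <= 100)).all()
    # sklearn-style params round-trip
    assert ImmunoscoreScorer(**scorer.get_params()).scale == scorer.scale


def test_scorer_with_fixed_cutoffs_needs_no_outcome(default_cohort_frame):
    out = ImmunoscoreScorer(cutoffs=UNIT_CUTS).fit(default_cohort_frame).transform(default_cohort_frame)
    assert len(out) == len(default_cohort_frame)


def test_scorer_rejects_partial_im(default_cohort_frame):
    df = default_cohort_frame.copy()
    df.loc[df.index[0], "cd3_im"] = np.nan
    df.loc[df.index[0], "cd8_im"] = 100.0
    with pytest.raises(ValidationError):
        ImmunoscoreScorer(cutoffs=UNIT_CUTS).fit(df)


def test_cutoff_model_json_roundtrip(tmp_path, default_cohort_frame):
    df = default_cohort_frame
    model = optimal_cutoffs(df, df["ttr_months"], df["ttr_event"])
    path = tmp_path / "cuts.json"
    model.to_json(path)
    back = CutoffModel.from_json(path)
    assert back.thresholds == pytest.approx(model.thresholds)
    assert back.scale == model.scale
    for c in DENSITY_COLUMNS:
        lo, hi = df[c].min(), df[c].max()
        assert lo < model.thresholds[c] < hi
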