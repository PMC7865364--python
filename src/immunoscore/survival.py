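"""Survival machinery: Kaplan-Meier, log-rank, stratified Cox, restricted
mean survival time, Wald-chi2 relative importance, Schoenfeld event sizing.

Kaplan-Meier curves (with log-log transformed confidence bands and
Brookmeyer-Crowley-style median CIs) and stratified Cox partial-likelihood
fits (Efron tie handling, Harrell C-index) are delegated to lifelines
behind dataclass surfaces shaped for cohort reporting.  The RMST two-sample
comparison and the chi2-proportion importance decomposition are computed
here from first principles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index, median_survival_times
from scipy import stats

from .exact import TestResult
from .scoring import ValidationError, two_group_logrank_thresholds


def _check_surv(times, events):
    times = np.asarray(times, float)
    events = np.asarray(events, float)
    if times.size == 0:
        raise ValidationError("need at least one subject")
    if times.size != events.size:
        raise ValidationError("times and events must have equal length")
    if (times < 0).any() or not np.isfinite(times).all():
        raise ValidationError("times must be finite and non-negative")
    if not np.isin(events, (0.0, 1.0)).all():
        raise ValidationError("events must be 0/1")
    return times, events


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class SurvEstimate:
    """Product-limit estimate with Greenwood variance, log-log 95% bands,
    median (inf = not reached) with CI, and survival rates at horizons."""

    table: pd.DataFrame  # time, at_risk, events, censored, survival, greenwood_var, ci_low, ci_high
    median: float
    median_ci: tuple[float, float]
    rates: dict[float, tuple[float, float, float]]
    n: int
    n_events: int

    def rate_at(self, horizon: float) -> tuple[float, float, float]:
        return self.rates[horizon]


def km_fit(times, events, horizons=(36.0, 60.0), alpha: float = 0.05) -> SurvEstimate:
    """Kaplan-Meier fit with Greenwood variance and horizon rates.

    Survival rates at each horizon are read off the step function with their
    log-log transformed confidence bounds; the median CI is where the
    confidence bands cross one half (Brookmeyer-Crowley convention).
    """
    times, events = _check_surv(times, events)
    if np.all(times == 0):
        raise ValidationError("all survival times are zero")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(times, events)
    et = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    ci = kmf.confidence_interval_

    d = et["observed"].to_numpy(float)
    n_risk = et["at_risk"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        increments = np.where(n_risk > d, d / (n_risk * (n_risk - d)), np.inf)
    increments = np.where(d > 0, increments, 0.0)
    greenwood = surv.to_numpy() ** 2 * np.cumsum(increments)

    table = pd.DataFrame(
        {
            "time": et.index.to_numpy(float),
            "at_risk": n_risk,
            "events": d,
            "censored": et["censored"].to_numpy(float),
            "survival": surv.to_numpy(),
            "greenwood_var": greenwood,
            "ci_low": ci.iloc[:, 0].to_numpy(),
            "ci_high": ci.iloc[:, 1].to_numpy(),
        }
    )

    median = float(kmf.median_survival_time_)
    med_ci = median_survival_times(kmf.confidence_interval_)
    median_ci = (float(med_ci.iloc[0, 0]), float(med_ci.iloc[0, 1]))

    rates = {}
    for h in horizons:
        s = float(kmf.predict(h))
        row = ci[ci.index <= h]
        if row.empty:
            lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
        else:
            lo, hi = float(row.iloc[-1, 0]), float(row.iloc[-1, 1])
        rates[float(h)] = (s, lo, hi)

    return SurvEstimate(
        table=table,
        median=median,
        median_ci=median_ci,
        rates=rates,
        n=int(times.size),
        n_events=int(events.sum()),
    )


def logrank_test(times, events, group) -> TestResult:
    """Log-rank test across >= 2 groups.

    For two groups the details carry the signed standardized statistic ``z``
    (observed minus expected events in the lexicographically later group),
    which the maximally selected cut-off search consumes.
    """
    times, events = _check_surv(times, events)
    group = np.asarray(group)
    labels = np.unique(group)
    if labels.size < 2:
        raise ValidationError("log-rank requires at least two groups")
    res = multivariate_logrank_test(times, group, events)
    details = {"labels": [str(x) for x in labels], "df": int(labels.size - 1)}
    if labels.size == 2:
        ind = (group == labels[1]).astype(float)
        z = two_group_logrank_thresholds(ind, times, events, np.array([0.5]))
        details["z"] = float(z[0])
    return TestResult(
        p_value=float(res.p_value),
        method="logrank",
        statistic=float(res.test_statistic),
        details=details,
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards (stratified, Efron ties)
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    """Stratified Cox fit: per-level hazard ratios, Harrell C, Wald chi2.

    ``summary`` rows: covariate, level, reference, hr, ci_low, ci_high,
    p, coef, se, flag ("" | "degenerate" | "separated").  Reference levels
    carry hr = 1 by construction and are not listed.  ``chi2`` holds the
    joint Wald chi-squared per covariate (all its levels at once).
    """

    summary: pd.DataFrame
    c_index: float
    c_index_ci: tuple[float, float] | None
    chi2: dict[str, float]
    events: int
    n: int
    strata: str | None
    params: pd.Series = field(repr=False, default=None)
    cov_matrix: pd.DataFrame = field(repr=False, default=None)
    design_columns: dict[str, list[str]] = field(default_factory=dict)


def _encode_design(
    df: pd.DataFrame, covariates: list[str], ref_levels: dict[str, str] | None
) -> tuple[pd.DataFrame, dict[str, list[str]], dict[str, str], list[tuple[str, str]]]:
    ref_levels = ref_levels or {}
    design = pd.DataFrame(index=df.index)
    columns: dict[str, list[str]] = {}
    references: dict[str, str] = {}
    degenerate: list[tuple[str, str]] = []
    for cov in covariates:
        col = df[cov]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            if col.nunique() == 1:
                degenerate.append((cov, "constant"))
                continue
            design[cov] = col.astype(float)
            columns[cov] = [cov]
            references[cov] = ""
            continue
        levels = sorted(map(str, col.dropna().unique()))
        ref = str(ref_levels.get(cov, levels[0]))
        if ref not in levels:
            raise ValidationError(f"reference level {ref!r} absent for covariate {cov!r}")
        others = [lv for lv in levels if lv != ref]
        if not others:
            degenerate.append((cov, ref))
            continue
        cols = []
        for lv in others:
            name = f"{cov}::{lv}"
            design[name] = (col.astype(str) == lv).astype(float)
            cols.append(name)
        columns[cov] = cols
        references[cov] = ref
    return design, columns, references, degenerate


def cox_fit(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str],
    strata: str | None = "center",
    ref_levels: dict[str, str] | None = None,
    n_boot_cindex: int = 0,
    seed: int = 0,
) -> CoxFit:
    """Stratified Cox partial-likelihood fit (Efron tie handling).

    Categorical covariates are dummy-encoded against an explicit reference
    level ("Unknown" is an ordinary level, never dropped); rows with missing
    values in the model variables are excluded complete-case.  Complete
    separation is flagged with a 0/inf hazard-ratio sentinel rather than an
    error; a constant covariate yields a flagged degenerate row (HR 1, p 1).
    """
    cols = [duration_col, event_col] + covariates + ([strata] if strata else [])
    for c in cols:
        if c not in df.columns:
            raise ValidationError(f"column {c!r} not in cohort")
    work = df[cols].dropna().copy()
    if work.empty or work[event_col].sum() < 1:
        raise ValidationError("no events available for Cox fit")
    design, columns, references, degenerate = _encode_design(work, covariates, ref_levels)
    fit_df = pd.concat(
        [work[[duration_col, event_col]].astype(float), design], axis=1
    )
    if strata:
        fit_df[strata] = work[strata].astype(str)

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            # separation is detected and flagged below; lifelines' advisory
            # warnings about it would otherwise flood batch runs
            warnings.simplefilter("ignore")
            cph.fit(
                fit_df,
                duration_col=duration_col,
                event_col=event_col,
                strata=[strata] if strata else None,
            )
    except Exception as exc:  # lifelines ConvergenceError and friends
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc

    summ = cph.summary
    rows = []
    for cov, colnames in columns.items():
        for name in colnames:
            coef = float(summ.loc[name, "coef"])
            se = float(summ.loc[name, "se(coef)"])
            p = float(summ.loc[name, "p"])
            level = name.split("::", 1)[1] if "::" in name else name
            flag = ""
            if abs(coef) > 10 or se > 50:  # complete or quasi-separation
                flag = "separated"
                hr = 0.0 if coef < 0 else math.inf
                lo, hi = 0.0, math.inf
            else:
                hr = math.exp(coef)
                lo = math.exp(coef - 1.959963984540054 * se)
                hi = math.exp(coef + 1.959963984540054 * se)
            rows.append(
                {
                    "covariate": cov, "level": level, "reference": references[cov],
                    "hr": hr, "ci_low": lo, "ci_high": hi, "p": p,
                    "coef": coef, "se": se, "flag": flag,
                }
            )
    for cov, ref in degenerate:
        rows.append(
            {
                "covariate": cov, "level": ref, "reference": ref,
                "hr": 1.0, "ci_low": np.nan, "ci_high": np.nan, "p": 1.0,
                "coef": 0.0, "se": np.nan, "flag": "degenerate",
            }
        )
    summary = pd.DataFrame(rows)

    V = cph.variance_matrix_
    beta = cph.params_
    chi2 = {}
    for cov, colnames in columns.items():
        b = beta.loc[colnames].to_numpy()
        sub = V.loc[colnames, colnames].to_numpy()
        try:
            chi2[cov] = float(b @ np.linalg.solve(sub, b))
        except np.linalg.LinAlgError:
            chi2[cov] = float("nan")

    c_index = float(cph.concordance_index_)
    c_ci = None
    if n_boot_cindex > 0:
        rng = np.random.default_rng(seed)
        lp = cph.predict_partial_hazard(fit_df).to_numpy()
        t = fit_df[duration_col].to_numpy()
        e = fit_df[event_col].to_numpy()
        vals = []
        for _ in range(n_boot_cindex):
            idx = rng.integers(0, len(t), size=len(t))
            if e[idx].sum() == 0:
                continue
            try:
                vals.append(concordance_index(t[idx], -lp[idx], e[idx]))
            except ZeroDivisionError:
                continue
        if vals:
            c_ci = (float(np.quantile(vals, 0.025)), float(np.quantile(vals, 0.975)))

    return CoxFit(
        summary=summary,
        c_index=c_index,
        c_index_ci=c_ci,
        chi2=chi2,
        events=int(work[event_col].sum()),
        n=int(len(work)),
        strata=strata,
        params=beta,
        cov_matrix=V,
        design_columns=columns,
    )


def chi2_importance(fit: CoxFit) -> dict[str, float]:
    """Relative importance of each covariate as its share of the total joint
    Wald chi-squared across covariates (shares in [0, 1], summing to 1)."""
    clean = {k: v for k, v in fit.chi2.items() if np.isfinite(v) and v >= 0}
    if not clean:
        raise ValidationError("no finite chi2 contributions in the fit")
    total = sum(clean.values())
    if total == 0:
        return {k: 1.0 / len(clean) for k in clean}
    return {k: v / total for k, v in clean.items()}


# ---------------------------------------------------------------------------
# restricted mean survival time
# ---------------------------------------------------------------------------


@dataclass
class RMSTResult:
    """Two-sample RMST comparison at truncation horizon tau (months).

    ``difference`` is arm1 minus arm0 where arms are the sorted group
    labels; a positive difference favours the later-sorted arm.
    """

    tau: float
    groups: tuple[str, str]
    rmst: dict[str, float]
    variance: dict[str, float]
    difference: float
    ci: tuple[float, float]
    p_value: float


def _rmst_single(times, events, tau: float) -> tuple[float, float]:
    """RMST (area under KM up to tau) and its large-sample variance.

    Variance is the standard sum over event times t_i <= tau of
    A_i^2 * d_i / (n_i (n_i - d_i)) with A_i the area under the curve from
    t_i to tau.
    """
    order = np.argsort(times, kind="mergesort")
    t, e = times[order], events[order]
    uniq = np.unique(t)
    s = 1.0
    prev = 0.0
    areas = []  # (area accumulated before this event time, S after, event info)
    event_rows = []
    rmst = 0.0
    n = len(t)
    at_risk = n
    i = 0
    for u in uniq:
        if u > tau:
            break
        block = (t == u)
        d = float(e[block].sum())
        c = float(block.sum() - d)
        rmst += s * (u - prev)
        if d > 0:
            event_rows.append((u, at_risk, d, rmst))
            s *= 1.0 - d / at_risk
        at_risk -= block.sum()
        prev = u
    rmst += s * (tau - prev)
    var = 0.0
    for u, n_i, d_i, area_before in event_rows:
        a_i = rmst - area_before  # integral of S from t_i to tau
        if n_i > d_i:
            var += (d_i / (n_i * (n_i - d_i))) * a_i**2
    return float(rmst), float(var)


def rmst_compare(times, events, group, tau: float | None = None, alpha: float = 0.05) -> RMSTResult:
    """Two-sample RMST difference with large-sample CI and z-test p-value.

    ``tau`` defaults to the smaller of the two per-arm largest observed
    times, the usual two-sample RMST convention; an explicit tau beyond an
    arm's follow-up is an error (the curve is unidentified there).
    """
    times, events = _check_surv(times, events)
    group = np.asarray(group)
    labels = np.unique(group)
    if labels.size != 2:
        raise ValidationError("rmst_compare requires exactly two groups")
    max_by_group = {lab: times[group == lab].max() for lab in labels}
    tau_max = min(max_by_group.values())
    if tau is None:
        tau = float(tau_max)
    elif tau > tau_max + 1e-12:
        raise ValidationError(
            f"tau={tau} exceeds the follow-up of a group (max common follow-up {tau_max:.4g})"
        )
    if tau <= 0:
        raise ValidationError("tau must be positive")
    est, var = {}, {}
    for lab in labels:
        m = group == lab
        est[str(lab)], var[str(lab)] = _rmst_single(times[m], events[m], tau)
    l0, l1 = str(labels[0]), str(labels[1])
    diff = est[l1] - est[l0]
    se = math.sqrt(var[l0] + var[l1])
    if diff == 0.0 and se == 0.0:
        z, p = 0.0, 1.0
        ci = (0.0, 0.0)
    else:
        z = diff / se if se > 0 else math.inf * np.sign(diff)
        p = 2.0 * stats.norm.sf(abs(z))
        zcrit = stats.norm.ppf(1 - alpha / 2)
        ci = (diff - zcrit * se, diff + zcrit * se)
    return RMSTResult(
        tau=float(tau),
        groups=(l0, l1),
        rmst=est,
        variance=var,
        difference=float(diff),
        ci=(float(ci[0]), float(ci[1])),
        p_value=float(p),
    )


# ---------------------------------------------------------------------------
# Schoenfeld event sizing
# ---------------------------------------------------------------------------


def schoenfeld_sample_size(
    hr: float,
    alpha: float = 0.05,
    sided: int = 2,
    power: float = 0.9,
    allocation: float = 0.5,
    event_fraction: float = 1.0,
) -> dict[str, float]:
    """Required number of events (and patients) to detect a hazard ratio.

    Schoenfeld's formula: events = (z_alpha + z_power)^2 /
    (allocation * (1 - allocation) * ln(hr)^2), with the alpha quantile
    one- or two-sided.  ``total_n`` divides by the anticipated event
    fraction; ``events`` and ``total_n`` are rounded up, ``raw_events``
    keeps the unrounded value.
    """
    if hr <= 0 or hr == 1.0:
        raise ValidationError("hr must be positive and different from 1")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValidationError("alpha and power must be in (0, 1)")
    if sided not in (1, 2):
        raise ValidationError("sided must be 1 or 2")
    if not 0 < allocation < 1:
        raise ValidationError("allocation must be in (0, 1)")
    if not 0 < event_fraction <= 1:
        raise ValidationError("event_fraction must be in (0, 1]")
    z_a = stats.norm.ppf(1 - alpha / sided)
    z_b = stats.norm.ppf(power)
    raw = (z_a + z_b) ** 2 / (allocation * (1 - allocation) * math.log(hr) ** 2)
    return {
        "raw_events": float(raw),
        "events": int(math.ceil(raw)),
        "total_n": int(math.ceil(raw / event_fraction)),
    }
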