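"""Exact contingency tests and two-sample density comparisons.

The association between Immunoscore categories and pathologic complete
response is tested exactly: Fisher's test for 2x2 tables and its
Freeman-Halton generalization for RxC tables.  Both use the classical
two-sided rule — sum the (multivariate) hypergeometric probabilities of all
tables with the observed margins whose probability does not exceed that of
the observed table (with a 1+1e-7 relative tolerance), which reproduces the
convention of standard statistical software to the printed precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .scoring import ValidationError

_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """Non-negative integer counts with labelled rows (score groups) and
    columns (response levels)."""

    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()
    excluded_n: int = 0  # patients dropped for missing values when cross-tabulating

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2:
            raise ValidationError("contingency table must be 2-dimensional")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("contingency counts must be integers")
            arr = np.round(arr).astype(np.int64)
        if (arr < 0).any():
            raise ValidationError("contingency counts must be non-negative")
        if arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValidationError("need at least 2 rows and 2 columns")
        object.__setattr__(self, "counts", arr.astype(np.int64))
        if not self.row_labels:
            object.__setattr__(self, "row_labels", tuple(f"row{i}" for i in range(arr.shape[0])))
        if not self.col_labels:
            object.__setattr__(self, "col_labels", tuple(f"col{j}" for j in range(arr.shape[1])))

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def column_percentages(self) -> np.ndarray:
        """Percentage of each column falling in each row (the reporting
        convention: % of responders / non-responders per score group)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.counts / self.col_margins[None, :]


@dataclass(frozen=True)
class TestResult:
    p_value: float
    method: str
    statistic: float | None = None
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value out of [0, 1]: {self.p_value}")


def _as_table(table) -> ContingencyTable:
    if isinstance(table, ContingencyTable):
        return table
    return ContingencyTable(np.asarray(table))


def _log_table_prob(counts: np.ndarray, row_m: np.ndarray, col_m: np.ndarray, logn: float) -> float:
    """Log multivariate hypergeometric probability of a margin-fixed table."""
    return float(
        gammaln(row_m + 1).sum() + gammaln(col_m + 1).sum() - logn - gammaln(counts + 1).sum()
    )


class EnumerationBudgetError(RuntimeError):
    """Exact enumeration would exceed the table budget; rerun with
    ``monte_carlo=<n_samples>`` (seeded) for a Monte-Carlo p-value."""


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test for a 2x2 table.

    Enumerates the hypergeometric distribution of the top-left cell with
    margins fixed and sums the probabilities of tables at most as probable
    as the observed one.
    """
    t = _as_table(table)
    if t.counts.shape != (2, 2):
        raise ValidationError("fisher_exact_2x2 requires a 2x2 table")
    if (t.row_margins == 0).any() or (t.col_margins == 0).any():
        raise ValidationError("degenerate margin: a row or column sums to zero")
    r1, r2 = t.row_margins
    c1, c2 = t.col_margins
    n = t.total
    logn = gammaln(n + 1)
    a_obs = t.counts[0, 0]
    a_min, a_max = max(0, r1 - c2), min(r1, c1)
    a = np.arange(a_min, a_max + 1)
    tables = np.stack([a, r1 - a, c1 - a, n - r1 - c1 + a], axis=1)
    logp = (
        gammaln(np.array([r1, r2]) + 1).sum()
        + gammaln(np.array([c1, c2]) + 1).sum()
        - logn
        - gammaln(tables + 1).sum(axis=1)
    )
    p_all = np.exp(logp)
    p_obs = p_all[a_obs - a_min]
    p = float(p_all[p_all <= p_obs * (1 + _REL_TOL)].sum())
    b, c, d = r1 - a_obs, c1 - a_obs, n - r1 - c1 + a_obs
    odds = np.inf if b * c == 0 else (a_obs * d) / (b * c)
    return TestResult(
        p_value=min(p, 1.0),
        method="fisher-exact-2x2",
        statistic=float(odds),
        details={"n": n, "tables": int(a.size)},
    )


def _row_compositions(total: int, bounds: list[int]):
    """Yield tuples of non-negative ints summing to ``total`` with
    cell j <= bounds[j]."""
    c = len(bounds)
    comp = [0] * c

    def rec(j: int, left: int):
        if j == c - 1:
            if left <= bounds[j]:
                comp[j] = left
                yield tuple(comp)
            return
        for v in range(min(left, bounds[j]) + 1):
            comp[j] = v
            yield from rec(j + 1, left - v)

    yield from rec(0, total)


def _enumerate_rxc(row_m, col_m, logn, p_cut, budget):
    """Sum probabilities of all margin-fixed tables with prob <= p_cut.

    Depth-first over rows; each non-final row is a bounded composition of
    its margin, the final row is determined by the remaining column margins.
    Returns (p_sum, n_tables_visited).
    """
    row_m = [int(x) for x in row_m]
    col_m = [int(x) for x in col_m]
    R, C = len(row_m), len(col_m)
    log_const = gammaln(np.asarray(row_m) + 1).sum() + gammaln(np.asarray(col_m) + 1).sum() - logn
    log_cut = np.log(p_cut) if p_cut > 0 else -np.inf
    state = {"p": 0.0, "count": 0}

    def rec(r: int, remaining: list[int], neg_log_fact: float):
        if r == R - 1:
            state["count"] += 1
            if state["count"] > budget:
                raise EnumerationBudgetError(
                    f"exact enumeration exceeded {budget} tables; "
                    "rerun with monte_carlo=<n_samples> and a seed"
                )
            logp = log_const + neg_log_fact - gammaln(np.asarray(remaining) + 1).sum()
            if logp <= log_cut:
                state["p"] += float(np.exp(logp))
            return
        for comp in _row_compositions(row_m[r], remaining):
            nxt = [remaining[j] - comp[j] for j in range(C)]
            rec(r + 1, nxt, neg_log_fact - float(gammaln(np.asarray(comp) + 1).sum()))

    rec(0, col_m, 0.0)
    return state["p"], state["count"]


def fisher_exact_rxc(
    table,
    max_tables: int = 2_000_000,
    monte_carlo: int | None = None,
    seed: int | None = None,
) -> TestResult:
    """Freeman-Halton exact test for an RxC table.

    Exact enumeration over all margin-fixed tables by default; when the
    enumeration budget ``max_tables`` would be exceeded an
    :class:`EnumerationBudgetError` instructs a seeded Monte-Carlo rerun
    (``monte_carlo`` null tables sampled by permutation, p-value reported
    with its Monte-Carlo standard error).
    """
    t = _as_table(table)
    # all-zero rows/columns admit exactly one configuration: drop them; a
    # table that collapses below 2x2 has a single attainable table (p = 1)
    counts = t.counts[t.row_margins > 0][:, t.col_margins > 0]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        return TestResult(
            p_value=1.0, method="freeman-halton-exact", statistic=None,
            details={"n": t.total, "tables": 1, "degenerate": True},
        )
    t = ContingencyTable(counts, excluded_n=t.excluded_n)
    n = t.total
    logn = gammaln(n + 1)
    p_obs = np.exp(_log_table_prob(t.counts, t.row_margins, t.col_margins, logn))
    p_cut = p_obs * (1 + _REL_TOL)

    if monte_carlo is not None:
        rng = np.random.default_rng(seed)
        rows = np.repeat(np.arange(t.counts.shape[0]), t.row_margins)
        cols = np.repeat(np.arange(t.counts.shape[1]), t.col_margins)
        hits = 0
        log_const = gammaln(t.row_margins + 1).sum() + gammaln(t.col_margins + 1).sum() - logn
        log_cut = np.log(p_cut)
        for _ in range(monte_carlo):
            perm = rng.permutation(cols)
            sim = np.zeros_like(t.counts)
            np.add.at(sim, (rows, perm), 1)
            logp = log_const - gammaln(sim + 1).sum()
            if logp <= log_cut:
                hits += 1
        p = (hits + 1) / (monte_carlo + 1)
        se = float(np.sqrt(p * (1 - p) / (monte_carlo + 1)))
        return TestResult(
            p_value=float(p),
            method="freeman-halton-monte-carlo",
            statistic=None,
            details={"n": n, "n_samples": monte_carlo, "mc_se": se, "seed": seed},
        )

    p, count = _enumerate_rxc(t.row_margins, t.col_margins, logn, p_cut, max_tables)
    return TestResult(
        p_value=float(min(p, 1.0)),
        method="freeman-halton-exact",
        statistic=None,
        details={"n": n, "tables": count},
    )


def two_sample_t(a, b, variant: str = "student") -> TestResult:
    """Two-sided two-sample t-test on densities.

    ``variant="student"`` pools variances; ``"welch"`` does not.  Degenerate
    zero-variance inputs are resolved deterministically: equal constant
    groups give p=1, unequal constant groups p=0 (flagged).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2 or not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("each group needs >= 2 finite values")
    if variant not in ("student", "welch"):
        raise ValidationError(f"unknown variant {variant!r}")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        degenerate = True
        p = 1.0 if a.mean() == b.mean() else 0.0
        stat = 0.0 if p == 1.0 else np.inf
        return TestResult(
            p_value=p, method=f"t-{variant}", statistic=float(stat), details={"degenerate": True}
        )
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return TestResult(
        p_value=float(res.pvalue),
        method=f"t-{variant}",
        statistic=float(res.statistic),
        details={"n_a": int(a.size), "n_b": int(b.size)},
    )


def crosstab(
    cohort: pd.DataFrame,
    row_var: str,
    col_var: str,
    drop_missing: bool = True,
    row_order: list[str] | None = None,
    col_order: list[str] | None = None,
) -> ContingencyTable:
    """Cross-tabulate two categorical cohort variables.

    Missing values (NaN / None) are dropped per-test (complete case) and the
    number of excluded patients recorded; explicit "Unknown" levels are kept
    as ordinary categories.
    """
    for var in (row_var, col_var):
        if var not in cohort.columns:
            raise ValidationError(f"variable {var!r} not in cohort")
    sub = cohort[[row_var, col_var]].copy()
    if drop_missing:
        before = len(sub)
        sub = sub.dropna()
        excluded = before - len(sub)
    else:
        excluded = 0
    if sub.empty:
        raise ValidationError(f"no patients with both {row_var!r} and {col_var!r} observed")
    tab = pd.crosstab(sub[row_var], sub[col_var])
    if row_order:
        tab = tab.reindex(index=[r for r in row_order if r in tab.index])
    if col_order:
        tab = tab.reindex(columns=[c for c in col_order if c in tab.columns])
    tab = tab.fillna(0).astype(int)
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValidationError("crosstab collapsed below 2x2: a variable is effectively constant")
    return ContingencyTable(
        counts=tab.to_numpy(),
        row_labels=tuple(map(str, tab.index)),
        col_labels=tuple(map(str, tab.columns)),
        excluded_n=excluded,
    )
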