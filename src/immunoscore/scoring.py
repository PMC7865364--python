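"""Immunoscore computation: densities -> percentiles -> IS / ISb categories.

The Immunoscore summarises adaptive immune infiltration of a tumor from the
densities (cells/mm^2) of CD3+ and CD8+ T cells measured in two regions, the
tumor center (CT) and the invasive margin (IM).  Each of the four
marker-by-region densities is dichotomised at a cohort-derived threshold;
the full score IS-0..IS-4 counts the number of "high" calls among the four,
and the biopsy-adapted score ISb-0..ISb-2 counts highs among the two CT
densities only (biopsies frequently lack an invasive margin).

Thresholds are determined by the optimal cut-off method: for each density
the candidate threshold maximising the absolute standardized log-rank
statistic between the resulting high/low groups on time to recurrence.

The cohort-facing entry point is :class:`ImmunoscoreScorer`, a
scikit-learn-style transformer (fit learns the percentile reference and the
cut-offs, transform assigns categories).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import SyntheticSlide

#: canonical order of the four marker-by-region densities
DENSITY_COLUMNS = ("cd3_ct", "cd8_ct", "cd3_im", "cd8_im")
CT_COLUMNS = ("cd3_ct", "cd8_ct")
IM_COLUMNS = ("cd3_im", "cd8_im")

IS_LABELS = ("IS-0", "IS-1", "IS-2", "IS-3", "IS-4")
ISB_LABELS = ("ISb-0", "ISb-1", "ISb-2")


class ValidationError(ValueError):
    """Invalid domain input (configuration, densities, table layout...)."""


@dataclass(frozen=True)
class DensityQuartet:
    """CD3/CD8 densities (cells/mm^2) in tumor center and invasive margin.

    IM densities are ``None`` when no invasive margin was present on the
    specimen; the two IM entries are missing together or not at all.
    """

    cd3_ct: float
    cd8_ct: float
    cd3_im: float | None = None
    cd8_im: float | None = None

    def __post_init__(self) -> None:
        for name in ("cd3_ct", "cd8_ct"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be a finite non-negative density, got {v!r}")
        im = [self.cd3_im, self.cd8_im]
        if (im[0] is None) != (im[1] is None):
            raise ValidationError("IM densities must be missing together (no partial invasive margin)")
        for name, v in zip(IM_COLUMNS, im):
            if v is not None and (not np.isfinite(v) or v < 0):
                raise ValidationError(f"{name} must be a finite non-negative density, got {v!r}")

    @property
    def im_present(self) -> bool:
        return self.cd3_im is not None

    def as_dict(self) -> dict[str, float | None]:
        return {c: getattr(self, c) for c in DENSITY_COLUMNS}


def quantify_density(slide: "SyntheticSlide", marker: str, region: str) -> float | None:
    """Density of ``marker`` points inside the ``region`` mask, in cells/mm^2.

    Returns ``None`` (missing, not an error) when the slide has no invasive
    margin and ``region`` is ``"im"``.
    """
    region = region.lower()
    marker = marker.lower()
    if region not in ("ct", "im"):
        raise ValidationError(f"unknown region {region!r}")
    if marker not in ("cd3", "cd8"):
        raise ValidationError(f"unknown marker {marker!r}")
    if region == "im" and not slide.im_present:
        return None
    mask = slide.masks[region]
    pts = slide.points[marker]
    x0, y0, x1, y1 = mask
    area = (x1 - x0) * (y1 - y0)
    if area <= 0:
        raise ValidationError("region mask has non-positive area")
    if len(pts) == 0:
        return 0.0
    inside = (
        (pts[:, 0] >= x0) & (pts[:, 0] <= x1) & (pts[:, 1] >= y0) & (pts[:, 1] <= y1)
    )
    return float(inside.sum() / area)


def empirical_percentile(x: float | np.ndarray, reference: Sequence[float]) -> float | np.ndarray:
    """Midrank empirical percentile of ``x`` within ``reference``, in [0, 100].

    Uses the tie-stable midrank convention
    ``100 * (#{r < x} + 0.5 * #{r = x}) / n``.
    """
    ref = np.asarray(reference, dtype=float)
    if ref.size == 0:
        raise ValidationError("empty percentile reference")
    return stats.percentileofscore(ref, x, kind="mean")


@dataclass
class PercentileReference:
    """Per marker-by-region sorted reference density vectors of a cohort."""

    vectors: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean = {}
        for name, v in self.vectors.items():
            arr = np.sort(np.asarray(v, dtype=float))
            if arr.size == 0:
                raise ValidationError(f"empty reference vector for {name}")
            clean[name] = arr
        self.vectors = clean

    @classmethod
    def from_frame(cls, densities: pd.DataFrame) -> "PercentileReference":
        vectors = {}
        for col in DENSITY_COLUMNS:
            vals = pd.to_numeric(densities[col], errors="coerce").dropna().to_numpy()
            vectors[col] = vals
        return cls(vectors)

    def percentile(self, column: str, x):
        return empirical_percentile(x, self.vectors[column])


def mean_percentile(percentiles: Mapping[str, float | None]) -> float:
    """Arithmetic mean of the available marker-by-region percentiles.

    All four are averaged when the invasive margin is present; the two CT
    percentiles otherwise.  Both CT percentiles are required.
    """
    for c in CT_COLUMNS:
        if percentiles.get(c) is None:
            raise ValidationError("both CT percentiles are required")
    avail = [percentiles[c] for c in DENSITY_COLUMNS if percentiles.get(c) is not None]
    return float(np.mean(avail))


# ---------------------------------------------------------------------------
# optimal cut-offs: maximally selected log-rank
# ---------------------------------------------------------------------------


def two_group_logrank_thresholds(
    values: np.ndarray, times: np.ndarray, events: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Signed standardized log-rank statistic of high (value >= g) vs low,
    for every candidate threshold g in ``grid``.

    The sign is (observed - expected) events in the high group: negative
    means the high group recurs less than expected.  Vectorised over the
    grid so a full cut-point search is a single pass over event times.
    """
    values = np.asarray(values, float)
    times = np.asarray(times, float)
    events = np.asarray(events, float)
    grid = np.asarray(grid, float)
    n = times.size
    order = np.argsort(-times, kind="mergesort")
    t_s, e_s = times[order], events[order]
    member = (values[order][:, None] >= grid[None, :]).astype(float)
    cum_at_risk = np.cumsum(member, axis=0)
    cum_events = np.cumsum(member * e_s[:, None], axis=0)

    change = np.nonzero(np.diff(t_s))[0]
    starts = np.r_[0, change + 1]
    ends = np.r_[change, n - 1]

    o_minus_e = np.zeros(grid.size)
    var = np.zeros(grid.size)
    for s, e in zip(starts, ends):
        d = e_s[s : e + 1].sum()
        if d == 0:
            continue
        n_risk = e + 1
        n1 = cum_at_risk[e]
        d1 = cum_events[e] - (cum_events[s - 1] if s > 0 else 0.0)
        frac = n1 / n_risk
        o_minus_e += d1 - d * frac
        if n_risk > 1:
            var += d * frac * (1.0 - frac) * (n_risk - d) / (n_risk - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, o_minus_e / np.sqrt(var), 0.0)
    return z


@dataclass
class CutoffModel:
    """Per marker-by-region dichotomisation thresholds.

    ``scale`` records whether thresholds live on the raw density scale
    (cells/mm^2) or on the cohort-percentile scale.  ``grids`` and ``traces``
    keep the candidate thresholds and their standardized log-rank statistics
    so a fit is auditable and reproducible.
    """

    thresholds: dict[str, float]
    scale: str = "density"
    grids: dict[str, np.ndarray] = field(default_factory=dict)
    traces: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in ("density", "percentile"):
            raise ValidationError(f"unknown cutoff scale {self.scale!r}")
        for name, thr in self.thresholds.items():
            if not np.isfinite(thr) or thr <= 0:
                raise ValidationError(f"threshold for {name} must be strictly positive, got {thr!r}")

    def to_json(self, path=None) -> str:
        payload = {
            "scale": self.scale,
            "thresholds": {k: float(v) for k, v in self.thresholds.items()},
            "grids": {k: np.asarray(v).tolist() for k, v in self.grids.items()},
            "traces": {k: np.asarray(v).tolist() for k, v in self.traces.items()},
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "CutoffModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                payload = json.loads(text)
            else:
                with open(text) as fh:
                    payload = json.load(fh)
        return cls(
            thresholds=payload["thresholds"],
            scale=payload.get("scale", "density"),
            grids={k: np.asarray(v) for k, v in payload.get("grids", {}).items()},
            traces={k: np.asarray(v) for k, v in payload.get("traces", {}).items()},
        )


def optimal_cutoff(
    values, times, events, grid_quantiles: tuple[float, float] = (0.10, 0.90)
) -> tuple[float, np.ndarray, np.ndarray]:
    """Maximally selected log-rank cut-point for a single density.

    Candidates are the observed unique values between the 10th and 90th
    percentile of the density distribution; the winner maximises the
    absolute standardized two-group log-rank statistic, ties broken toward
    the candidate nearest the median.  Returns (threshold, grid, z-trace).
    """
    values = np.asarray(values, float)
    times = np.asarray(times, float)
    events = np.asarray(events, float)
    mask = np.isfinite(values)
    values, times, events = values[mask], times[mask], events[mask]
    if values.size == 0 or np.ptp(values) == 0:
        raise ValidationError("degenerate density distribution")
    if events.sum() < 1:
        raise ValidationError("no events: cut-off search undefined")
    lo, hi = np.quantile(values, grid_quantiles)
    grid = np.unique(values)
    grid = grid[(grid >= lo) & (grid <= hi)]
    if grid.size == 0:
        raise ValidationError("degenerate density distribution")
    z = two_group_logrank_thresholds(values, times, events, grid)
    best = np.abs(z).max()
    candidates = grid[np.isclose(np.abs(z), best, rtol=1e-9, atol=0.0)]
    med = np.median(values)
    threshold = float(candidates[np.argmin(np.abs(candidates - med))])
    return threshold, grid, z


def optimal_cutoffs(
    densities: pd.DataFrame,
    times,
    events,
    scale: str = "density",
    grid_quantiles: tuple[float, float] = (0.10, 0.90),
    min_events: int = 20,
) -> CutoffModel:
    """Fit maximally selected log-rank cut-offs for all four densities.

    Patients missing a given density (no invasive margin) are dropped for
    that density's search only.  Requires at least ``min_events`` observed
    events on the outcome used (time to recurrence in the study design).
    ``scale="percentile"`` runs the search on cohort midrank percentiles.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, float)
    if events.sum() < min_events:
        raise ValidationError(
            f"need >= {min_events} events for a stable cut-off search, got {int(events.sum())}"
        )
    work = densities[list(DENSITY_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    if scale == "percentile":
        ref = PercentileReference.from_frame(work)
        work = pd.DataFrame(
            {c: np.where(np.isfinite(work[c]), ref.percentile(c, work[c].fillna(0.0)), np.nan) for c in DENSITY_COLUMNS}
        )
    thresholds, grids, traces = {}, {}, {}
    for col in DENSITY_COLUMNS:
        thr, grid, z = optimal_cutoff(work[col].to_numpy(), times, events, grid_quantiles)
        thresholds[col], grids[col], traces[col] = thr, grid, z
    return CutoffModel(thresholds=thresholds, scale=scale, grids=grids, traces=traces)


# ---------------------------------------------------------------------------
# category assignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImmunoscoreResult:
    """Percentiles, mean percentile and IS/ISb category calls for one patient.

    ``is_category`` counts high calls among all four densities (0-4) and is
    ``None`` (unclassified) when the invasive margin is missing;
    ``isb_category`` counts highs among the two CT densities (0-2) and is
    always defined.  Collapsed groupings mirror the reporting convention:
    three-level IS {IS-0, IS-1-2, IS-3-4}, two-level IS {IS-0-2, IS-3-4},
    two-level ISb {ISb-0, ISb-1-2}.
    """

    percentiles: dict[str, float | None]
    mean_percentile: float
    is_category: int | None
    isb_category: int

    @property
    def is_label(self) -> str | None:
        return None if self.is_category is None else IS_LABELS[self.is_category]

    @property
    def isb_label(self) -> str:
        return ISB_LABELS[self.isb_category]

    @property
    def is3_group(self) -> str | None:
        if self.is_category is None:
            return None
        return "IS-0" if self.is_category == 0 else ("IS-1-2" if self.is_category <= 2 else "IS-3-4")

    @property
    def is2_group(self) -> str | None:
        if self.is_category is None:
            return None
        return "IS-0-2" if self.is_category <= 2 else "IS-3-4"

    @property
    def isb2_group(self) -> str:
        return "ISb-0" if self.isb_category == 0 else "ISb-1-2"


def assign_categories(
    quartet: DensityQuartet,
    cutoffs: CutoffModel,
    reference: PercentileReference | None = None,
) -> ImmunoscoreResult:
    """Assign IS and ISb categories from one patient's density quartet.

    A density is "high" when it is >= its threshold (closed at the
    threshold).  When ``cutoffs.scale == "percentile"`` the quartet is first
    converted with ``reference``; percentiles are reported either way when a
    reference is supplied.
    """
    values = quartet.as_dict()
    if reference is not None:
        percentiles = {
            c: (None if values[c] is None else float(reference.percentile(c, values[c])))
            for c in DENSITY_COLUMNS
        }
    else:
        percentiles = {c: None for c in DENSITY_COLUMNS}
    if cutoffs.scale == "percentile":
        if reference is None:
            raise ValidationError("percentile-scale cutoffs require a PercentileReference")
        compare = percentiles
    else:
        compare = values
    highs = {
        c: (None if compare[c] is None else compare[c] >= cutoffs.thresholds[c])
        for c in DENSITY_COLUMNS
    }
    isb = int(sum(bool(highs[c]) for c in CT_COLUMNS))
    if quartet.im_present:
        is_cat: int | None = int(sum(bool(highs[c]) for c in DENSITY_COLUMNS))
    else:
        is_cat = None
    if reference is not None:
        mp = mean_percentile(percentiles)
    else:  # no reference: mean of raw-scale "pseudo-percentiles" is meaningless; use NaN
        mp = float("nan")
    return ImmunoscoreResult(
        percentiles=percentiles, mean_percentile=mp, is_category=is_cat, isb_category=isb
    )


class ImmunoscoreScorer(BaseEstimator, TransformerMixin):
    """Cohort-level Immunoscore transformer.

    fit(X, y) learns the percentile reference from the cohort densities and,
    unless fixed ``cutoffs`` were supplied, the optimal (maximally selected
    log-rank) thresholds against the survival outcome ``y``.  transform(X)
    returns a DataFrame with percentiles, mean percentile, IS/ISb categories
    and the collapsed groups.

    Parameters
    ----------
    scale : {"density", "percentile"}
        Scale on which thresholds are searched and applied.
    grid_quantiles : (low, high)
        Quantile window restricting cut-point candidates, default (0.1, 0.9).
    cutoffs : CutoffModel, optional
        Fixed externally supplied thresholds; skips the cut-point search.
    min_events : int
        Minimum number of events required to fit cut-offs.
    """

    def __init__(
        self,
        scale: str = "density",
        grid_quantiles: tuple[float, float] = (0.10, 0.90),
        cutoffs: CutoffModel | None = None,
        min_events: int = 20,
    ):
        self.scale = scale
        self.grid_quantiles = grid_quantiles
        self.cutoffs = cutoffs
        self.min_events = min_events

    def fit(self, X: pd.DataFrame, y=None):
        """X: DataFrame with the four density columns; y: (n, 2) array-like of
        (time, event) for the outcome driving the cut-point search (ignored
        when fixed cutoffs were supplied)."""
        X = self._check_X(X)
        self.reference_ = PercentileReference.from_frame(X)
        if self.cutoffs is not None:
            self.cutoffs_ = self.cutoffs
        else:
            if y is None:
                raise ValidationError("y=(time, event) is required to fit optimal cut-offs")
            y = np.asarray(y, float)
            if y.ndim != 2 or y.shape[1] != 2:
                raise ValidationError("y must be an (n, 2) array of (time, event)")
            self.cutoffs_ = optimal_cutoffs(
                X, y[:, 0], y[:, 1], scale=self.scale,
                grid_quantiles=self.grid_quantiles, min_events=self.min_events,
            )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "cutoffs_"):
            raise ValidationError("ImmunoscoreScorer is not fitted")
        X = self._check_X(X)
        rows = []
        for _, row in X.iterrows():
            q = DensityQuartet(
                cd3_ct=row["cd3_ct"],
                cd8_ct=row["cd8_ct"],
                cd3_im=None if pd.isna(row["cd3_im"]) else row["cd3_im"],
                cd8_im=None if pd.isna(row["cd8_im"]) else row["cd8_im"],
            )
            r = assign_categories(q, self.cutoffs_, reference=self.reference_)
            rows.append(
                {
                    **{f"pct_{c}": r.percentiles[c] for c in DENSITY_COLUMNS},
                    "mean_percentile": r.mean_percentile,
                    "is_category": r.is_category,
                    "isb_category": r.isb_category,
                    "is_label": r.is_label,
                    "isb_label": r.isb_label,
                    "is3_group": r.is3_group,
                    "is2_group": r.is2_group,
                    "isb2_group": r.isb2_group,
                }
            )
        out = pd.DataFrame(rows, index=X.index)
        out["is_category"] = out["is_category"].astype("Int64")
        return out

    @staticmethod
    def _check_X(X: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in DENSITY_COLUMNS if c not in X.columns]
        if missing:
            raise ValidationError(f"missing density columns: {missing}")
        X = X[list(DENSITY_COLUMNS)].apply(pd.to_numeric, errors="coerce")
        if X[list(CT_COLUMNS)].isna().any().any():
            raise ValidationError("CT densities must be present for every analyzable patient")
        if (X < 0).any().any():
            raise ValidationError("densities must be non-negative")
        partial = X["cd3_im"].isna() != X["cd8_im"].isna()
        if partial.any():
            raise ValidationError("IM densities must be missing together")
        return X
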