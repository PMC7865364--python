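"""Seeded synthetic cohorts of neoadjuvant-treated muscle-invasive bladder
cancer patients.

The generator emulates the statistical structure the Immunoscore analysis
assumes, so that every downstream stage (scoring, exact tests, survival
models) is exercisable without patient data:

* a latent per-patient immune level drives correlated right-skewed
  (log-normal) CD3/CD8 densities in tumor center and invasive margin,
  the probability of a pathologic complete response (logistic in the mean
  density percentile), and the recurrence hazard (proportional hazards in
  the latent immune category and nodal stage);
* overall survival is recurrence time plus an exponential post-recurrence
  survival, guaranteeing TTR <= OS and correlated endpoints;
* censoring is administrative at a fixed horizon plus uniform early dropout;
* invasive margins and the pCR flag are missing completely at random at
  configurable rates, and clinical covariates carry explicit "Unknown"
  levels at the cohort-table rates of the study design.

Default parameter values reproduce the published cohort's marginal
characteristics (n=117, 77.8% male, five centers, ~30% pCR, 13.7% pCR
missing, ...).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .scoring import DENSITY_COLUMNS, DensityQuartet, ValidationError, empirical_percentile


class ParseError(ValueError):
    """Malformed cohort file."""


# Cohort-table categorical rates (probability of each level, "Unknown" last
# where the study reports a not-available fraction).
_CATEGORICALS: dict[str, tuple[tuple[str, float], ...]] = {
    "gender": (("Male", 0.778), ("Female", 0.222)),
    "tobacco": (("No", 0.231), ("Yes", 0.667), ("Unknown", 0.102)),
    "toxic_exposure": (("No", 0.641), ("Yes", 0.085), ("Unknown", 0.274)),
    "prior_bcg": (("No", 0.795), ("Yes", 0.205)),
    "t_stage": (("T2", 0.906), ("T3-4", 0.060), ("Unknown", 0.034)),
    "n_stage": (("N0", 0.265), ("N+", 0.658), ("Unknown", 0.077)),
    "histology": (("UC", 0.846), ("Variant", 0.145), ("Unknown", 0.009)),
    "regimen": (("MVAC", 0.564), ("GC", 0.376), ("Carboplatin", 0.026), ("OtherPlatinum", 0.034)),
}

_CENTERS = ("Lille", "HEGP", "IMM", "Diaconnesses", "Alexandra")


def _default_center_probs() -> tuple[float, ...]:
    return (0.077, 0.171, 0.419, 0.231, 0.102)


def _default_location() -> dict[str, float]:
    # log cells/mm^2; medians ~ exp(loc): CD3-CT 200, CD8-CT 100, CD3-IM 330, CD8-IM 150
    return {"cd3_ct": 5.3, "cd8_ct": 4.6, "cd3_im": 5.8, "cd8_im": 5.0}


def _default_scale() -> dict[str, float]:
    return {c: 1.0 for c in DENSITY_COLUMNS}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    ``immune_effect_pcr`` is the log-odds of pCR per unit mean percentile/100;
    ``immune_effect_ttr`` the log-hazard *reduction* per latent immune-score
    level (hazard multiplier exp(-effect * level)); hazards are per month.
    """

    n_patients: int = 117
    center_probs: tuple[float, ...] = field(default_factory=_default_center_probs)
    immune_effect_pcr: float = 2.5
    immune_effect_ttr: float = 0.5
    baseline_hazard_ttr: float = 0.035
    baseline_hazard_os: float = 0.05
    density_log_location: dict[str, float] = field(default_factory=_default_location)
    density_log_scale: dict[str, float] = field(default_factory=_default_scale)
    latent_corr: float = 0.6
    variant_im_shift: float = -1.0  # log-scale IM deficit of variant histologies, in SD units
    n_stage_log_hr_ttr: float = 0.7
    pcr_base_rate: float = 0.35  # marginal pCR probability at mean percentile 50
    frac_missing_im: float = 0.15
    frac_missing_pcr: float = 0.137
    admin_censor_months: float = 72.0
    dropout_frac: float = 0.80
    age_mean: float = 66.4
    age_sd: float = 8.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.n_patients, (int, np.integer)) and self.n_patients >= 0):
            raise ValidationError(f"n_patients must be a non-negative integer, got {self.n_patients!r}")
        probs = np.asarray(self.center_probs, float)
        if probs.size < 2 or (probs < 0).any() or not np.isclose(probs.sum(), 1.0, atol=1e-6):
            raise ValidationError("center_probs must be a probability vector over >= 2 centers")
        for name in ("baseline_hazard_ttr", "baseline_hazard_os", "admin_censor_months"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{name} must be positive, got {v!r}")
        for name in ("frac_missing_im", "frac_missing_pcr", "dropout_frac"):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v!r}")
        if not 0.0 <= self.latent_corr < 1.0:
            raise ValidationError(f"latent_corr must be in [0, 1), got {self.latent_corr!r}")
        if not 0.0 < self.pcr_base_rate < 1.0:
            raise ValidationError("pcr_base_rate must be in (0, 1)")
        for name in ("immune_effect_pcr", "immune_effect_ttr", "variant_im_shift", "n_stage_log_hr_ttr"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")
        for table in (self.density_log_location, self.density_log_scale):
            for c in DENSITY_COLUMNS:
                if c not in table or not np.isfinite(table[c]):
                    raise ValidationError(f"density parameter missing or non-finite for {c}")
        if any(s <= 0 for s in self.density_log_scale.values()):
            raise ValidationError("density_log_scale entries must be positive")

    def replace(self, **kw) -> "CohortConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    center: str
    gender: str
    tobacco: str
    toxic_exposure: str
    prior_bcg: str
    age_years: float
    t_stage: str
    n_stage: str
    histology: str
    regimen: str
    densities: DensityQuartet
    pcr: str | None  # "yes" / "no" / None (missing)
    ttr_months: float
    ttr_event: int
    os_months: float
    os_event: int

    def __post_init__(self) -> None:
        if self.ttr_months < 0 or self.os_months < 0:
            raise ValidationError("survival times must be non-negative")
        if self.ttr_months > self.os_months + 1e-9:
            raise ValidationError("ttr_months must not exceed os_months")
        if self.ttr_event not in (0, 1) or self.os_event not in (0, 1):
            raise ValidationError("event flags must be 0/1")
        if self.pcr not in ("yes", "no", None):
            raise ValidationError(f"pcr must be 'yes', 'no' or None, got {self.pcr!r}")


@dataclass(frozen=True)
class SyntheticSlide:
    """Rectangular region masks (mm, as (x0, y0, x1, y1)) with marked CD3/CD8
    point sets; ``im_present=False`` drops the IM mask and its points."""

    masks: dict[str, tuple[float, float, float, float]]
    points: dict[str, np.ndarray]
    im_present: bool = True


def _draw_categorical(rng: np.random.Generator, levels, n: int) -> np.ndarray:
    labels = [lv for lv, _ in levels]
    probs = np.array([p for _, p in levels], float)
    probs = probs / probs.sum()
    return rng.choice(labels, size=n, p=probs)


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Generate a seeded synthetic cohort; deterministic given config+seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    if n == 0:
        return []

    centers = rng.choice(
        _CENTERS[: len(config.center_probs)], size=n,
        p=np.asarray(config.center_probs) / np.sum(config.center_probs),
    )
    cats = {name: _draw_categorical(rng, levels, n) for name, levels in _CATEGORICALS.items()}
    age = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 40.0, 85.0)

    # latent immune level -> correlated log-normal densities
    latent = rng.standard_normal(n)
    loading = np.sqrt(config.latent_corr)
    noise_sd = np.sqrt(1.0 - config.latent_corr)
    log_dens = {}
    for c in DENSITY_COLUMNS:
        loc, sc = config.density_log_location[c], config.density_log_scale[c]
        eps = rng.standard_normal(n)
        shift = np.where(
            (cats["histology"] == "Variant") & (c in ("cd3_im", "cd8_im")),
            config.variant_im_shift * sc,
            0.0,
        )
        log_dens[c] = loc + shift + sc * (loading * latent + noise_sd * eps)
    dens = {c: np.exp(v) for c, v in log_dens.items()}

    # latent immune category: high calls at the generating medians
    latent_is = sum(
        (log_dens[c] > config.density_log_location[c]).astype(int) for c in DENSITY_COLUMNS
    )

    # pCR: logistic in the cohort mean percentile / 100
    pcts = {c: np.asarray(empirical_percentile(dens[c], dens[c]), float) for c in DENSITY_COLUMNS}
    mean_pct = np.mean([pcts[c] for c in DENSITY_COLUMNS], axis=0)
    eta = (
        np.log(config.pcr_base_rate / (1 - config.pcr_base_rate))
        + config.immune_effect_pcr * (mean_pct / 100.0 - 0.5)
    )
    p_pcr = 1.0 / (1.0 + np.exp(-eta))
    pcr_true = rng.random(n) < p_pcr

    # recurrence: exponential PH in latent IS level and nodal stage
    log_hz = (
        np.log(config.baseline_hazard_ttr)
        - config.immune_effect_ttr * latent_is
        + config.n_stage_log_hr_ttr * (cats["n_stage"] == "N+")
    )
    t_rec = rng.exponential(1.0 / np.exp(log_hz))
    # death follows recurrence after an exponential post-recurrence survival
    t_death = t_rec + rng.exponential(1.0 / config.baseline_hazard_os, size=n)

    # censoring: administrative horizon, with early uniform dropout for a fraction
    cens = np.full(n, config.admin_censor_months)
    dropout = rng.random(n) < config.dropout_frac
    cens[dropout] = rng.uniform(0.0, config.admin_censor_months, size=int(dropout.sum()))

    ttr_months = np.minimum(t_rec, cens)
    ttr_event = (t_rec <= cens).astype(int)
    os_months = np.minimum(t_death, cens)
    os_event = (t_death <= cens).astype(int)

    im_missing = rng.random(n) < config.frac_missing_im
    pcr_missing = rng.random(n) < config.frac_missing_pcr

    records = []
    for i in range(n):
        quartet = DensityQuartet(
            cd3_ct=float(dens["cd3_ct"][i]),
            cd8_ct=float(dens["cd8_ct"][i]),
            cd3_im=None if im_missing[i] else float(dens["cd3_im"][i]),
            cd8_im=None if im_missing[i] else float(dens["cd8_im"][i]),
        )
        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:04d}",
                center=str(centers[i]),
                gender=str(cats["gender"][i]),
                tobacco=str(cats["tobacco"][i]),
                toxic_exposure=str(cats["toxic_exposure"][i]),
                prior_bcg=str(cats["prior_bcg"][i]),
                age_years=float(np.round(age[i], 1)),
                t_stage=str(cats["t_stage"][i]),
                n_stage=str(cats["n_stage"][i]),
                histology=str(cats["histology"][i]),
                regimen=str(cats["regimen"][i]),
                densities=quartet,
                pcr=None if pcr_missing[i] else ("yes" if pcr_true[i] else "no"),
                ttr_months=float(np.round(ttr_months[i], 4)),
                ttr_event=int(ttr_event[i]),
                os_months=float(np.round(os_months[i], 4)),
                os_event=int(os_event[i]),
            )
        )
    return records


def generate_slide(
    density_targets: DensityQuartet,
    ct_area_mm2: float = 2.0,
    im_area_mm2: float = 1.0,
    seed: int = 0,
) -> SyntheticSlide:
    """Homogeneous Poisson point pattern with the requested expected densities.

    Counts per marker-by-region are Poisson(density * area); points are
    uniform inside axis-aligned rectangular masks.  When the target quartet
    has no invasive margin, the IM mask and its points are dropped.
    """
    if ct_area_mm2 <= 0 or im_area_mm2 <= 0:
        raise ValidationError("mask areas must be positive")
    rng = np.random.default_rng(seed)
    im_present = density_targets.im_present
    # CT rectangle at origin; IM rectangle placed to the right, disjoint
    ct_w = float(np.sqrt(ct_area_mm2))
    im_w = float(np.sqrt(im_area_mm2))
    masks = {"ct": (0.0, 0.0, ct_w, ct_w)}
    if im_present:
        masks["im"] = (ct_w + 0.5, 0.0, ct_w + 0.5 + im_w, im_w)

    targets = {
        ("cd3", "ct"): density_targets.cd3_ct,
        ("cd8", "ct"): density_targets.cd8_ct,
        ("cd3", "im"): density_targets.cd3_im,
        ("cd8", "im"): density_targets.cd8_im,
    }
    points: dict[str, list[np.ndarray]] = {"cd3": [], "cd8": []}
    for (marker, region), target in targets.items():
        if region == "im" and not im_present:
            continue
        area = ct_area_mm2 if region == "ct" else im_area_mm2
        count = rng.poisson(target * area)
        x0, y0, x1, y1 = masks[region]
        pts = np.column_stack(
            [rng.uniform(x0, x1, size=count), rng.uniform(y0, y1, size=count)]
        )
        points[marker].append(pts)
    merged = {m: (np.vstack(v) if v else np.empty((0, 2))) for m, v in points.items()}
    return SyntheticSlide(masks=masks, points=merged, im_present=im_present)


# ---------------------------------------------------------------------------
# cohort table I/O
# ---------------------------------------------------------------------------

COHORT_COLUMNS = (
    "patient_id", "center", "gender", "age_years", "tobacco", "toxic_exposure",
    "prior_bcg", "t_stage", "n_stage", "histology", "regimen",
    "cd3_ct", "cd8_ct", "cd3_im", "cd8_im",
    "pcr", "ttr_months", "ttr_event", "os_months", "os_event",
)


def cohort_to_frame(cohort: list[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in cohort:
        d = r.densities
        rows.append(
            {
                "patient_id": r.patient_id, "center": r.center, "gender": r.gender,
                "age_years": r.age_years, "tobacco": r.tobacco,
                "toxic_exposure": r.toxic_exposure, "prior_bcg": r.prior_bcg,
                "t_stage": r.t_stage, "n_stage": r.n_stage, "histology": r.histology,
                "regimen": r.regimen,
                "cd3_ct": d.cd3_ct, "cd8_ct": d.cd8_ct,
                "cd3_im": np.nan if d.cd3_im is None else d.cd3_im,
                "cd8_im": np.nan if d.cd8_im is None else d.cd8_im,
                "pcr": r.pcr if r.pcr is not None else np.nan,
                "ttr_months": r.ttr_months, "ttr_event": r.ttr_event,
                "os_months": r.os_months, "os_event": r.os_event,
            }
        )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def frame_to_cohort(df: pd.DataFrame) -> list[PatientRecord]:
    records = []
    for idx, row in df.iterrows():
        try:
            quartet = DensityQuartet(
                cd3_ct=float(row["cd3_ct"]),
                cd8_ct=float(row["cd8_ct"]),
                cd3_im=None if pd.isna(row["cd3_im"]) else float(row["cd3_im"]),
                cd8_im=None if pd.isna(row["cd8_im"]) else float(row["cd8_im"]),
            )
            pcr = row["pcr"]
            records.append(
                PatientRecord(
                    patient_id=str(row["patient_id"]), center=str(row["center"]),
                    gender=str(row["gender"]), tobacco=str(row["tobacco"]),
                    toxic_exposure=str(row["toxic_exposure"]), prior_bcg=str(row["prior_bcg"]),
                    age_years=float(row["age_years"]), t_stage=str(row["t_stage"]),
                    n_stage=str(row["n_stage"]), histology=str(row["histology"]),
                    regimen=str(row["regimen"]), densities=quartet,
                    pcr=None if pd.isna(pcr) else str(pcr),
                    ttr_months=float(row["ttr_months"]), ttr_event=int(row["ttr_event"]),
                    os_months=float(row["os_months"]), os_event=int(row["os_event"]),
                )
            )
        except (ValidationError, ValueError, TypeError) as exc:
            raise ParseError(f"invalid cohort row {idx} (patient {row.get('patient_id')!r}): {exc}") from exc
    return records


def write_cohort(cohort: list[PatientRecord], path) -> None:
    """Write a cohort CSV (one row per patient; empty cell = missing)."""
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort(path) -> list[PatientRecord]:
    """Read a cohort table (CSV, or a .xlsx spreadsheet with the same columns)."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"malformed header: missing columns {missing}")
    for col in ("cd3_ct", "cd8_ct", "cd3_im", "cd8_im", "ttr_months", "os_months", "age_years"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ParseError(f"non-numeric value in column {col!r} at row {bad[0]}")
        df[col] = coerced
    return frame_to_cohort(df)
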