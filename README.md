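# immunoscore

Immunoscore analysis for localized muscle-invasive bladder cancer (MIBC)
treated with neoadjuvant platinum-based chemotherapy: CD3+/CD8+ T-cell
density scoring, association with pathologic complete response (pCR), and
time-to-recurrence (TTR) / overall-survival (OS) stratification — packaged
as a tested, reproducible pipeline that runs end-to-end on seeded synthetic
cohorts.

It is written for biostatisticians and translational researchers who want
the full analytic chain of an Immunoscore study as reusable, verifiable
code: density quantification, percentile scoring, optimal cut-point search,
exact contingency tests, and survival modelling.

## The score and the statistics

The Immunoscore summarises adaptive immune infiltration from four densities
(cells/mm²): CD3+ and CD8+ T cells in the tumor center (CT) and the
invasive margin (IM). Each density is converted to a cohort midrank
percentile, `100·(#{r < x} + ½·#{r = x})/n`, and dichotomised at a
threshold found by the **optimal cut-off method**: the candidate maximising
the absolute standardized two-group log-rank statistic on TTR over the
observed values between the 10th and 90th percentile. Counting "high" calls
gives

- **IS-0 … IS-4** over all four densities (undefined when the IM is
  missing, as in many biopsy specimens), and
- **ISb-0 … ISb-2**, the biopsy-adapted score over the two CT densities.

Downstream the package provides:

- **Exact contingency tests** — Fisher's 2×2 exact test and its
  Freeman–Halton R×C generalisation by full margin-fixed enumeration
  (two-sided rule: sum of hypergeometric probabilities ≤ observed, with a
  1 + 1e-7 relative tolerance), plus a seeded Monte-Carlo fallback for
  large tables;
- **Survival machinery** — Kaplan–Meier with Greenwood variance, log-log
  confidence bands and Brookmeyer–Crowley median CIs; log-rank tests;
  center-stratified Cox models (Efron ties, Harrell C-index); two-sample
  restricted mean survival time (RMST) with the standard large-sample
  variance; per-covariate Wald-χ² importance shares; and Schoenfeld event
  sizing `D = (z_α + z_β)² / (π(1−π) ln²HR)`;
- **A synthetic cohort generator** whose defaults reproduce the marginal
  structure of a 117-patient neoadjuvant MIBC cohort (77.8% male, five
  centers, ~30% pCR with 13.7% missing, ~15% missing invasive margins,
  immune-dependent pCR odds and recurrence hazards, OS ≥ TTR).

## Worked example

```python
from immunoscore import RunConfig, run

rep = run(RunConfig(seed=1))          # simulate a default 117-patient cohort

blk = rep.contingency["isb_3group"]
print(blk["counts"], round(blk["p_value"], 4))
# [[31, 6], [20, 6], [16, 20]] 0.0009

biv = rep.bivariable["ttr"]["is3_group"]
print(round(biv["cox"]["IS-3-4"]["hr"], 2),
      round(biv["levels"]["IS-3-4"]["rates"]["60"]["rate"], 1),
      round(biv["levels"]["IS-0"]["rates"]["60"]["rate"], 1))
# 0.2 45.9 7.1

print({k: round(v, 2) for k, v in rep.multivariable["ttr"]["chi2_shares"].items()})
# {'isb_label': 0.63, 'gender': 0.0, 'toxic_exposure': 0.02,
#  'histology': 0.08, 't_stage': 0.05, 'n_stage': 0.22}
```

Reading the output: the 3×2 ISb-by-pCR table is tested with the
Freeman–Halton exact test (p = 0.0009 — in this simulated cohort a high
biopsy Immunoscore is strongly associated with achieving a pCR); patients
scored IS-3–4 recur at a fraction of the IS-0 hazard (HR 0.2) with a far
higher five-year recurrence-free rate (45.9% vs 7.1%); and in the
multivariable model the Immunoscore carries the dominant share (63%) of the
Wald χ² across all covariates.

The same pipeline is scriptable from the shell:

```sh
immunoscore simulate --n 117 --seed 1 --out cohort.csv
immunoscore run --seed 1 --out results/ --figures
immunoscore make-fixtures --out fixtures/
```

An estimator-style interface is available for composition with
scikit-learn: `ImmunoscoreScorer(...).fit(densities, y=(time, event))`
learns the percentile reference and cut-offs, `.transform(densities)`
returns percentiles and IS/ISb categories.

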