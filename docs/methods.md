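# Methods

This note documents the models, conventions and numerical choices behind
the package, what the synthetic cohort generator does and does not emulate,
and the known limitations.

## Scoring model

Four densities (cells/mm²) enter the score: CD3+ and CD8+ T cells in the
tumor center (CT) and the invasive margin (IM). Two constructions are kept
side by side because both are used in practice:

- **Mean percentile** — each density is converted to a cohort midrank
  percentile `100·(#{r < x} + ½·#{r = x})/n` and the available percentiles
  (four, or the two CT ones when the IM is absent) are averaged. The
  midrank convention is symmetric and tie-stable; it feeds the pCR model as
  a continuous covariate. Under this formula a value strictly below every
  reference is percentile 0 and the reference minimum itself sits at 50/n.
- **Categorical calls** — each density is called high when it is **≥** its
  threshold (closed at the threshold, so ties resolve deterministically).
  IS-0…IS-4 counts highs among all four densities and is *unclassified*
  when the IM is missing; ISb-0…ISb-2 counts highs among the CT pair and is
  always defined. Collapsed groupings {IS-0, IS-1–2, IS-3–4},
  {IS-0–2, IS-3–4} and {ISb-0, ISb-1–2} mirror the reporting convention.

Categories are defined as counts of per-density high calls rather than by
cutting the mean percentile: the count definition is the only fully
specified rule ("low density of both populations in both localizations" up
to "elevated densities of both populations in both localizations"), and it
makes the monotonicity and IS/ISb consistency properties exact.

**Cut-offs.** The optimal cut-off per density maximises the absolute
standardized two-group log-rank statistic on time to recurrence over a
candidate grid of the observed unique values restricted to the [q10, q90]
window (boundary thresholds produce tiny groups and unstable statistics).
Ties in the maximal statistic break toward the candidate nearest the
median. At least 20 observed events are required. The search runs on the
raw density scale by default; a percentile-scale search is available, and a
fixed externally supplied `CutoffModel` (serialized to JSON with its grid
and statistic trace) bypasses the search entirely — this is how a frozen
reference is applied to new patients. The percentile reference defaults to
the analysis cohort itself, matching a single-cohort retrospective design.

Maximally selected statistics are multiplicity-inflated: under no
association the selected split's log-rank p-value is anti-conservative.
The package therefore treats outcome-optimised thresholds as descriptive
(as the original design does) and uses outcome-free thresholds (cohort
medians, or the generator's known location parameters) wherever a test
needs nominal operating characteristics — e.g. the null-calibration checks
in the test suite.

## Exact contingency tests

Fisher's 2×2 test enumerates the hypergeometric distribution of one cell
with margins fixed; the Freeman–Halton R×C generalisation enumerates all
margin-fixed tables depth-first (bounded row compositions, last row
determined). Both use the two-sided rule "sum the probabilities of tables
at most as probable as the observed one", with a 1 + 1e-7 relative
tolerance on the comparison — the convention of mainstream statistical
software, which reproduces published 4-decimal p-values bit-for-bit.
All-zero rows or columns admit a single configuration and are dropped; a
table that collapses below 2×2 has exactly one attainable table and p = 1.
Enumeration is guarded by an explicit table budget; beyond it a seeded
Monte-Carlo version (null tables sampled by permutation) reports p with its
Monte-Carlo standard error. The two-sample t-test on densities defaults to
the pooled-variance form with Welch available (the historical choice
between them is typically unstated in reports; both are exposed).
No multiple-testing correction is applied anywhere: raw p-values are
reported, as in the study design this package mirrors.

## Survival analysis

- **Kaplan–Meier** via lifelines, with Greenwood variance
  `S(t)² Σ d/(n(n−d))` computed from the event table, log-log transformed
  95% bands, and the median CI read where the bands cross ½
  (Brookmeyer–Crowley convention); "not reached" is represented as
  infinity and rendered "NR". Horizon rates (default 36 and 60 months) are
  step-function lookups with their band values.
- **Cox models** are center-stratified partial-likelihood fits with Efron
  tie handling (the default of the R ecosystem such studies use, and more
  accurate than Breslow). Categorical covariates are dummy-encoded against
  explicit reference levels; "Unknown" is an ordinary level, never dropped.
  A constant covariate yields a flagged degenerate row (HR 1, p 1); a
  separated level (|coef| > 10 or SE > 50) is flagged with a 0/inf
  hazard-ratio sentinel rather than an error, since sparse "Unknown" levels
  separate routinely in cohorts of this size. Harrell's C-index comes from
  the fitted linear predictor; its CI, when requested, is a seeded
  bootstrap over patients with the predictor held fixed.
- **RMST** is the exact step integral of the KM curve to τ, with the
  standard large-sample variance `Σ A_i² d_i/(n_i(n_i−d_i))` where `A_i` is
  the area under the curve from the i-th event time to τ. τ defaults to the
  smaller of the two per-arm largest observed times (the usual two-sample
  convention); a τ beyond an arm's follow-up is an error. The difference is
  reported arm1 − arm0 over sorted labels with a z-test.
- **χ² importance** divides each covariate's joint Wald χ²
  (`βᵀV⁻¹β` over its levels) by the total across covariates; shares lie in
  [0, 1] and sum to 1.
- **Schoenfeld sizing**: `D = (z_α + z_β)²/(π(1−π) ln²HR)`, with total n =
  ⌈D/event fraction⌉. With 60% events, 90% power, HR 1.85–2.1 and 1:1
  allocation this yields 151–104 patients under a *one-sided* 5% α and
  187–128 under a two-sided α. A published range of "103–152" for these
  inputs is consistent only with the one-sided form (to within ±1 from
  rounding order), even when described as two-tailed; the `sided` argument
  makes the choice explicit rather than resolving it silently.
- Median follow-up uses the reverse Kaplan–Meier method (censorings as
  events), the common convention where the method is unstated.

## Synthetic cohort generator

The generator is the package's test bed: it produces cohorts with the
statistical structure the analysis assumes, calibrated to the marginal
characteristics of a 117-patient neoadjuvant MIBC cohort.

A standard-normal latent immune level A drives everything immune:

- **Densities** are log-normal, `log d = μ_c + σ_c(√ρ·A + √(1−ρ)·ε)`,
  with per-density locations (medians ≈ 200/100/330/150 cells/mm² for
  CD3-CT/CD8-CT/CD3-IM/CD8-IM), unit log-scales and latent correlation
  ρ = 0.6 across the four densities. Variant histologies carry a −1.0 SD
  IM deficit, sized so the documented density contrast (n ≈ 99 vs 17) is
  detectable with ~97% power at the 5% level.
- **pCR** is logistic in the cohort mean percentile/100 with slope 2.5
  (log-odds) around a 35% marginal rate — reproducing the observed
  gradient from ~18% response in score-low to ~50%+ in score-high patients.
- **Recurrence** is exponential proportional hazards, 0.035/month baseline,
  hazard multiplied by `exp(−0.5·L)` per latent immune level L (the count
  of densities above their generating medians) and by `exp(0.7)` for
  nodal involvement. Over the ~3.5-level span between score-high and
  score-low this reproduces a high-vs-low hazard ratio of ≈ 0.15.
- **Death** occurs at the recurrence time plus an exponential
  post-recurrence survival (rate 0.05/month). This guarantees TTR ≤ OS and
  correlated endpoints; it is a modelling convenience, not a claim about
  the joint law, which such studies never specify.
- **Censoring** is administrative at 72 months, with 80% of patients
  additionally subject to uniform early dropout — a stand-in for staggered
  accrual. The resulting median follow-up (reverse KM) is ≈ 36–48 months,
  deliberately longer than the ≈ 27–31 months of the motivating design so
  the 3- and 5-year horizon rates the reports print remain estimable from
  a single simulated cohort.
- **Missingness** is completely at random: invasive margins missing with
  probability 0.15 (the motivating cohort reports both 21/117 missing-IM
  specimens and 14 unclassified patients — irreconcilable as printed, so
  the rate is exposed as a parameter between the two), pCR missing with
  probability 0.137, and "Unknown" covariate levels at the cohort-table
  rates. The cohort table also prints N+ 77/117 yet a bivariable block with
  N+ 8/39; defaults follow the cohort table.

Synthetic slides are homogeneous Poisson point patterns in rectangular CT
and IM masks with expectation density×area, for round-trip testing of the
density quantification; they make no attempt at realistic histology or
spatial clustering.

**What passing tests show.** The generator reproduces marginal category
frequencies, a monotone immune–pCR link, proportional-hazards recurrence
with recoverable coefficients, and MCAR missingness. It does not emulate
center-level effect heterogeneity, competing risks, informative (outcome-
dependent) missingness, measurement error in densities, or inter-observer
variation — so green tests validate the *statistical machinery* under the
stated model, not robustness of the score on real slides.

## Pipeline and reporting

`run(RunConfig)` executes: cohort acquisition (simulate or load) → cut-off
fit → IS/ISb assignment → pCR contingency tests → per-covariate bivariable
TTR/OS blocks (KM medians and 3-/5-year rates, center-stratified Cox, RMST
vs reference) → multivariable stratified Cox (ISb 3-group + gender + toxic
exposure + histology + T + N, "Unknown" levels kept) → χ² shares →
serialized report. Bivariable blocks are complete-case per covariate and
exclude "Unknown" (as bivariable reports do); the multivariable model keeps
"Unknown" as levels. Markdown output rounds p-values to 4 and rates to 1
decimal (print precision); JSON keeps full precision. Reports contain no
timestamps; given identical configuration and seed they are byte-identical,
and provenance records the seed, package version, fitted thresholds and a
SHA-256 of the canonical configuration.

The packaged fixtures are generated programmatically: a 100-patient frame
encoding the published score-vs-response cross-tabulation exactly (10 of
its patients IM-missing, so ISb tests use n = 100 and IS tests n = 90),
with covariates and outcomes drawn from a fixed-seed generator to avoid
accidental collinearity; a fixed threshold file (100 cells/mm² per
density, between the frame's low/high values 50 and 200); and a
hand-checkable six-subject KM example.

## Degenerate inputs and numerical conventions

- Densities must be finite and non-negative; IM densities are missing
  together or not at all; CT densities are required for any analyzable
  patient.
- All-identical densities or zero observed events make the cut-off search
  error ("degenerate density distribution" / insufficient events).
- Zero-variance t-test groups: equal constant groups give p = 1, unequal
  p = 0, both flagged degenerate.
- A zero margin is an error for the 2×2 exact test; the R×C test reduces
  the table instead (see above).
- Log-rank variance terms with n = 1 at risk are skipped; RMST variance
  terms with n_i = d_i are skipped (Greenwood convention).
- Seeds: every stochastic component takes an explicit seed
  (`numpy.random.default_rng`); the pipeline threads one seed through
  generation, bootstrap and Monte-Carlo fallbacks.

## Problem sizes

Simulation-backed checks in the test suite use cohorts of 400–2000
patients and 40–100 seeded replicates per property — large enough that
closed-form targets sit within 2–3 standard errors and coverage/recovery
rates have low Monte-Carlo noise, while the default suite and the
acceptance script each complete in a few minutes.

## Limitations

- Time to recurrence censors at death without recurrence; competing risks
  (Fine–Gray) are out of scope and recurrence-free fractions at long
  horizons should be read accordingly.
- No proportional-hazards diagnostics beyond the RMST comparison, which is
  provided precisely because it is PH-assumption-free.
- The C-index bootstrap resamples patients against a fixed linear
  predictor; it ignores refit variability.
- Percentile references and cut-offs learned on a cohort of ~100 patients
  are noisy; the packaged machinery reproduces the design faithfully but
  inherits its small-sample instability.
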