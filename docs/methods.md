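# Methods

## The audit model

A clinical audit measures *documentation*, not biology: each audit item asks
whether a guideline-relevant action (a diagnosis criterion, a symptom score,
a vaccination, a prescription) is recorded in the medical chart. The unit of
analysis is the audited case; cases nest in primary care centers, centers in
regions. An item's performance is the fraction of eligible cases for which
the action is documented, reported at cohort, center and region level.

### Patient-level rules

* **Diagnosis.** A case counts as correctly diagnosed when (i) at least one
  inhalational exposure is documented (active-smoking history, passive
  smoking, occupational, biomass, other) and (ii) airflow obstruction is
  present at the *last recorded visit* — obstruction at diagnosis alone does
  not establish non-reversibility. Obstruction is FEV₁/FVC < 70 % (fixed
  ratio, strict inequality, configurable). The audited-visit spirometry is
  the post-bronchodilator test when one exists, else the pre-bronchodilator
  test (the source is reported); with neither, the obstruction component
  fails. A missing ratio is recomputed from FEV₁ and FVC when both volumes
  are recorded; with no usable data the obstruction check is *indeterminate*,
  which the diagnosis rule treats as not demonstrated. A stricter variant
  additionally requires a registered respiratory-symptom evaluation; we
  define "symptoms" as dyspnea or chronic cough/sputum registration and
  exclude asthma-symptom registration, which serves a differential purpose.
* **GOLD 2017 group.** High symptom burden is mMRC ≥ 2 or CAT ≥ 10; high risk
  is ≥ 2 exacerbations or ≥ 1 hospitalization in the previous year. A case is
  unclassifiable when both symptom scores are unknown or the exacerbation
  count is unknown. An unknown hospitalization count with a known
  exacerbation count contributes zero risk rather than making the case
  unclassifiable: the exacerbation count alone is a valid (if conservative)
  risk assessment, whereas the converse — inferring *low* risk from absent
  exacerbation data — is not.
* **Regimens.** Prescription lines are multisets over {LABA, LAMA, ICS} (a
  fixed-dose combination contributes each component once per line). The
  de-duplicated set maps exhaustively to seven categories; {ICS, LAMA} is
  kept as its own category (`LAMA_ICS_other`) because that non-combined
  pairing is clinically noteworthy, while the rendered treatment table folds
  it into "ICS + one long-acting bronchodilator". Duplication (any component
  appearing on more than one line) is detected on the multiset *before*
  de-duplication.
* **Incorrect prescriptions.** Three scenarios, each with a reason code:
  GOLD B–D with no maintenance medication; ICS monotherapy in any group;
  duplicated components. Group A without medication is acceptable.
* **Comorbidity.** Charlson uses the original, non-age-adjusted weights: a
  cohort of mean age ≈ 71 with a mean index near 2 is only consistent with
  the non-age-adjusted version (age adjustment alone would add ≥ 3 points).
  The COTE index weights COPD-relevant conditions (lung/esophageal/pancreatic
  cancer 6, anxiety 6 in women only, other cancers 2, cirrhosis 4, atrial
  fibrillation 2, diabetes with neuropathy 2, pulmonary fibrosis 2, CHF 1,
  peptic ulcer 1, coronary artery disease 1). Both weight tables ship as
  versioned YAML (`coach_audit/data/comorbidity_vocab.yaml`) so weights are
  data, not code; unknown condition codes are rejected by name. Coronary
  artery disease belongs to both the cardiac and the vascular group;
  "psychiatric" reflects psychotropic-drug use, "eyedrops" is a marker of eye
  disease.

### Aggregation and banding

Adequacy bands follow the convention excellent (> 80 %), good (60–80 %),
adequate (40–59 %), inadequate (20–39 %), highly inadequate (< 20 %). The
printed band edges are ambiguous at 59–60 and at exactly 80; we use half-open
intervals with 80.0 → good, because the top band is printed strictly
"> 80 %". Banding always uses the unrounded percentage (display rounding
could otherwise promote 79.96 to "excellent"); reported percentages are
rounded half-up to one decimal. A zero denominator yields an undefined-rate
marker, never an exception.

Inter-center and inter-regional ranges are the lowest and highest unit-level
percentages. Centers with fewer than 10 audited cases are excluded (their
rates are too unstable to bound the range); the region-level minimum defaults
to 30 cases — the smallest analysis unit one level up should exceed the
center minimum meaningfully — and is configurable. Excluded units are listed
in the result, and an empty eligible set yields an undefined-range marker.

### Variability testing

For quantitative variables the Levene test (classic form, centered on group
means — not the median-based Brown–Forsythe variant; configurable) gates the
dispatch: one-way ANOVA under homoscedasticity, Welch's heteroscedastic
one-way test otherwise (statsmodels `anova_oneway`, `use_var="unequal"`).
Categorical variables use Pearson's chi-square of homogeneity without
continuity correction (most comparisons involve far more than two groups;
correction is available for 2×2). α = 0.05 two-tailed. No multiple-testing
correction is applied across items, mirroring standard audit reporting; the
rendered report carries a note to that effect. Degenerate inputs follow one
policy: data with no variance anywhere (all-constant groups, a one-column
contingency table after dropping empty categories) return statistic 0,
p = 1 — no evidence of heterogeneity — rather than raising, so synthetic
edge cases cannot crash the dispatch. Groups with fewer than two usable
observations are dropped; malformed tables (negative counts, zero margins)
are input errors.

## The synthetic generator

The generator emulates the *documentation patterns* of a nationwide audit
database, not disease biology: no progression, exacerbation dynamics or
treatment response is modeled.

* **Hierarchy.** `n_regions × centers_per_region` centers with
  `cases_per_center` cases each (defaults 6 × 10 × 80, matching a design of
  80 audited cases per center). Center populations are drawn log-uniformly
  over `rural_population_range` (default 2 000–600 000), and a center is
  rural when its population is below 25 000; the default range puts roughly
  40 % of centers in the rural class.
* **Cluster effects.** Every binary item receives independent per-center and
  per-region Gaussian offsets on the logit scale (SDs `center_effect_sd`,
  `region_effect_sd`). The magnitude of real cluster effects is unknown;
  the defaults 0.4 and 0.2 are illustrative values that produce wide,
  clearly significant inter-center ranges like those seen in practice, and
  both knobs are exercised down to 0 (the null generator) in tests. The
  intercept is *calibrated*: for prevalence p and total effect SD σ we solve
  E[expit(a + σZ)] = p by Newton iteration on 41-node Gauss–Hermite
  quadrature, so the configured prevalence is the marginal rate (the naive
  intercept logit(p) drifts by up to ~2 points at the default SDs). At σ = 0
  this reduces exactly to logit(p). Categorical distributions (sex, smoking
  status, regimen, GOLD group) perturb per-category log-probabilities and
  renormalize; their residual bias is below one point at the default SDs.
* **Outcome-first construction.** Rates that downstream rules must recover
  are drawn first and the record is constructed to realize them: a case drawn
  "correctly diagnosed" gets documented exposure plus an obstructive
  audited-visit spirometry (post-BD with probability 0.09, else pre-BD);
  a "not correct" case with documented exposure gets either no audited-visit
  spirometry or a non-obstructive one. Nested items use conditional
  probabilities derived from the configured marginals (e.g. vaccination
  administered given registered; mMRC registration given exacerbation
  registration is set so that P(both) equals `gold_classifiable_fraction`,
  default 0.101), so pooled marginals reproduce the configured values in
  expectation; infeasible combinations are rejected at config validation.
* **Continuous variables.** Age, FEV₁ (mL and % predicted), FEV₁/FVC, BMI
  and pack-years are Gaussian with configured means/SDs, truncated by
  resampling to physiologic ranges (age 35–100 y, FEV₁ 300–5000 mL,
  FEV₁ % 15–130, ratio 20–95 %, BMI 14–55 kg/m², pack-years 0–150). Centers
  shift a variable's location by `u · SD · κ` with κ = 0.25 by default and
  κ = 0 for the FEV₁ variables, so lung function shows no center
  heterogeneity — between-center variation in documentation need not be
  driven by disease severity, and the FEV₁-homogeneous default lets that
  contrast be simulated.
* **Reproducibility.** The single global seed expands into independent
  per-center substreams (`numpy.random.SeedSequence.spawn`), so a cohort is
  byte-identical for a fixed (config, seed) and independent of center
  iteration order. `generate_item_counts` / `generate_continuous_values`
  follow the same hierarchy for single variables, making replicate-heavy
  calibration studies cheap.

### What the generator does not emulate

Items are independent across patients given the cluster effects; real charts
correlate documentation quality within a patient. Treatment is independent of
GOLD group (the real gradient of ICS use across groups is absent). All
centers contribute equal case counts, so the small-center exclusion rule is
exercised by hand-built fixtures rather than by the generator. Passing tests
therefore demonstrate the correctness and calibration of the *pipeline*, not
fidelity to any real cohort.

## Problem sizes used in the checks

The statistical calibration studies use 63 centers × 68 cases (≈ 4 300
cases, the scale of the motivating audit) with 1000 replicates for the
type-I-error checks, and 10 seeds of the full 63 × 68 cohort for the
parameter-recovery check (tolerance ± 1.5 percentage points on the pooled
rate, which covers the residual categorical bias and seed-to-seed noise).
`scripts/acceptance.py` reruns the chi-square calibration from scratch with
a user-supplied seed.

## Known limitations

* The band edges at 59–60 % and 80 % and the spirometric obstruction cutoff
  (fixed ratio vs. lower limit of normal) are conventions chosen here;
  both are configurable.
* Welch-vs-ANOVA dispatch is applied uniformly per variable; with many small
  groups the Levene gate itself consumes α and the combined procedure is only
  approximately calibrated (empirically within [0.03, 0.07] at α = 0.05).
* No mixed-effects or intraclass-correlation estimation of the cluster
  effect is provided; the variability statistics describe heterogeneity
  without attributing causes.
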