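# Methods

## Decision model

The engine is a deterministic knowledge-based rule set over one
hospitalization record. Screening removes patients under 18 years, patients
without type 2 diabetes (type 1 reported with its own reason code), and
patients already receiving an agent of the class being considered
(case-insensitive class-level match against shipped molecule/brand/ATC
dictionaries; combination products count). For screened patients:

| parameter | default | comparison | meaning |
|---|---|---|---|
| `bmi_glp1_solo_threshold` | 28 kg/m² | strictly above | GLP-1RA solo pathway |
| `bmi_glp1_cvd_threshold` | 25 kg/m² | strictly above | GLP-1RA pathway with CVD |
| `egfr_sglt2i_contra` | 30 mL/min/1.73 m² | strictly below | SGLT2i contraindication |
| `egfr_glp1ra_contra` | 15 mL/min/1.73 m² | strictly below | GLP-1RA contraindication |
| `min_age` | 18 years | below | screening exclusion |
| `obesity_threshold` | 30 kg/m² | strictly above | obesity composite |

Boundary values (BMI exactly 28, eGFR exactly 30) therefore fall on the
permissive side. Contraindications are evaluated before eligibility, so a
contraindicated patient is never recommended regardless of qualifying
conditions, and all applicable contraindication reasons are reported
together. A missing BMI (GLP-1RA) or eGFR (SGLT2i) produces
`indeterminate` — the fail-safe reading of missing data. HbA1c is never
consulted while `hba1c_disregarded` is true (the default); the national
formulary's HbA1c gates (7.0% / 7.5%) are retained as documented constants
and can be switched back on.

Genuinely open design points, fixed as follows:

* **"CVD" in the GLP-1RA pathway**: defined as ASCVD ∪ heart failure by
  default (`cvd_definition="ascvd_plus_hf"`), configurable to ASCVD-only.
  The broad reading matches the guideline usage of "cardiovascular disease";
  the comorbidity definitions elsewhere name only ASCVD, so both are exposed.
* **SGLT2i with no qualifying condition**: not recommended by default
  (`sglt2i_requires_indication=True`); a permissive variant (type 2 diabetes
  alone suffices) is available because formulary indications include it.
* **MEN2**: optional GLP-1RA contraindication, off by default, since the
  deployed rule list names only pancreatitis, pancreatic cancer, medullary
  thyroid cancer, and low eGFR.
* **eGFR from creatinine**: a CKD-EPI 2021 fall-back is shipped but disabled
  by default; the deployed system read eGFR directly from the EMR.

## Comorbidity extraction

Flags are set by ICD-10 prefix match (codes normalized to uppercase, dot
removed) or case-insensitive keyword substring over problem-list strings —
no NLP, so matching is deterministic, order-independent, and idempotent. The
shipped dictionary (`data/default_codemap.yaml`) uses standard ICD-10
prefixes; it is a reasonable default, not a claim about any particular
hospital's dictionary, and every operation accepts a caller-supplied map.
Scope choices are documented in the YAML itself: the cancer flag excludes
in-situ disease and non-melanoma skin cancer; moderate–severe CKD is
code-driven at stage ≥ 3b (N18.4/N18.5) — eGFR governs contraindications
separately in the engine. Composites: ASCVD = IHD ∪ cerebrovascular ∪
peripheral vascular disease; obesity = BMI > 30; moderate–severe liver
disease supersedes mild.

The Charlson comorbidity index uses the original 1987 weights with no age
adjustment; within a category only the highest weight counts (metastatic over
non-metastatic cancer, complicated over uncomplicated diabetes,
moderate–severe over mild liver disease).

The free-text discharge diagnosis is categorized by first keyword match in
the fixed priority order diabetes complication > heart failure > IHD >
ischemic stroke > CKD > other; the order resolves multi-condition strings
deterministically and is a package choice.

## Cohort handling

Period assignment keys on the **discharge** date (the recommendation event
occurs at discharge) against inclusive window bounds; the default windows are
1 Jan–31 Dec 2021 (pre) and 1 Apr–6 Oct 2023 (post). Deduplication keeps the
earliest admission per (patient, period) — a patient may appear once in each
period — with ties broken by input order for determinism. CSV/JSONL round
trips are lossless; missing numeric values are empty cells / nulls, never
sentinel numbers.

## Statistics

* **Odds ratios.** The reporting path is the crude cross-product OR with the
  Wald interval on the log scale (z = 1.959964 for 95%) and a two-sided Wald
  p. For a single binary covariate this equals the logistic MLE, which is
  also implemented (statsmodels GLM/IRLS) and cross-checked in the tests to
  ≤ 1e-6 relative. Tables with a zero cell get the Haldane–Anscombe +0.5
  correction with an explicit method flag (stratified reports can contain 0%
  arms); a zero margin yields a flagged degenerate estimate with interval
  (0, ∞) rather than an exception.
* **Categorical comparisons.** Pearson chi-square without the Yates
  correction by default; Fisher's exact (scipy, the
  sum-of-no-more-probable-tables two-sided convention, verified against full
  hypergeometric enumeration) when any expected cell is below 5 or a margin
  is zero.
* **Continuous comparisons.** Each arm is screened with a Kolmogorov–Smirnov
  test against a normal law with the sample's own mean and SD at α = 0.05
  (using estimated parameters makes the screen conservative toward
  normality; with the audit's group sizes the routing is stable); both pass →
  Welch's unequal-variance t-test, otherwise Wilcoxon rank-sum. Arms with
  fewer than 3 observations are an error; a zero-variance arm routes to
  Wilcoxon.
* Two-sided α = 0.05 throughout, no multiplicity adjustment — mirroring
  standard audit reporting. Subgroup output is a forest-table layout with
  per-stratum pre/post rates and ORs; the age cut places a 75-year-old in the
  older stratum.

## Synthetic cohort generator

The generator emulates the *eligible* cohort (the post-filter population the
audit reports on) directly, per period:

* age truncated-normal (floor 18; defaults 74.2 ± 11.7 and 71.3 ± 12.5
  years), length of stay log-normal with μ = log(median) and σ from the
  log-quartile spread (defaults median 3, IQR 2–6 vs median 4, IQR 3–7 days),
  discharge date uniform in the period window;
* comorbidity flags as independent Bernoulli draws at the configured
  prevalences (defaults are the audit's baseline-table columns, e.g. ASCVD
  60.8% vs 47.2%, obesity 20.3% vs 32.5%); ASCVD is drawn as the composite
  and realized through one component; contraindication prevalences are not
  published and default to small realistic rates (pancreatitis 1%,
  pancreatic cancer 0.2%, medullary thyroid cancer 0.05%);
* BMI is drawn conditionally on the obesity flag (truncated normal above or
  below 30) so the obesity prevalence is exact by construction; eGFR is
  truncated normal, lower for records with the CKD flag;
* ICD codes are back-filled from the code map's first prefix per flag, so the
  mapper reproduces the drawn flags exactly;
* the physician-recommendation label is an independent Bernoulli draw at the
  configured per-period probability (defaults 8.5% / 22.7%) — in the study
  design the outcome is physician behavior, which is distinct from the
  algorithm's output, and the generator models that distinction explicitly.

A draw the engine would not recommend for either class is minimally
repaired rather than rejected (rejection distorts the configured marginals
badly when indications are rare): first choice is raising BMI into the
(28, 30] band (creates the GLP-1RA solo pathway without flipping the obesity
composite), then re-drawing a contraindicating eGFR into 45–90, then adding
heart failure when a hard GLP-1RA contraindication blocks the BMI route.
Repair counts are reported in the cohort metadata; under the default
configuration repairs touch ~17–21% of records (almost all BMI raises), and
the calibration tests verify the flag marginals still sit inside exact
binomial bands (Bonferroni-adjusted across the 18 flag × period comparisons
to keep the family error at 1%).

What the generator does **not** emulate: correlation between comorbidities
(marginals only; a correlation hook is out of scope), association between the
outcome label and patient covariates within a period (labels are
period-conditional Bernoulli), free-text clinical notes beyond keyword stubs,
longitudinal structure, or missing-data patterns (labs are always present by
default). Passing calibration therefore shows the pipeline recovers the
configured marginal composition and rates — not that the generator reproduces
real EMR dependence structure.

`generate_worked_fixture()` returns a deterministic 25-record hand-built
cohort covering every decision status for both classes, every reason code,
and the boundary values; it is shipped as `data/worked_fixture.jsonl` with a
golden decision table (produced by an independent truth-table oracle) under
`tests/data/`.

## Verification problem sizes

The oracle-equivalence check runs the engine against an independently coded
brute-force truth table over the full cross-product of the six
decision-relevant flags × BMI ∈ {24, 25, 25.1, 28, 28.1, 35, missing} ×
eGFR ∈ {10, 14.9, 15, 29.9, 30, 60, missing} (3,136 combinations), with
exclusion axes (diabetes type, age, prior treatment) exercised on a reduced
grid. Fisher's exact p is compared with full hypergeometric enumeration
exhaustively for all tables with n ≤ 24 (20,475 tables) plus 1,000 random
tables with 24 < n ≤ 60. Simulator calibration uses 10,000 records per
period for rates and 2,000 replicates at the study's group sizes
(1,318/970) for Wald-interval coverage, expected in 93–97%.

## Known limitations

* The shipped ICD/keyword dictionary is a generic default; site-specific
  coding practice (especially free-text conventions) will need a custom map.
* The engine is class-level: molecule selection, dosing, drug–drug
  interactions, and reimbursement adjudication are out of scope.
* The statistics module implements univariate contrasts only — no
  stepped-wedge mixed models, adjustment, or interrupted-time-series
  analysis.
* Synthetic cohorts are calibration tools, not realistic EMR simulations
  (see above).
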