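# File formats and vocabularies

## Cohort column dictionary (CSV / JSONL)

One row (CSV) or JSON object (JSONL) per hospitalization. CSV is UTF-8,
comma-delimited, ISO-8601 dates; multi-valued cells are semicolon-separated;
a missing value is an empty cell (CSV) or `null` (JSONL) — never a sentinel
number. JSONL uses native lists.

| column | type | notes |
|---|---|---|
| `patient_id` | string | opaque identifier; mandatory |
| `admission_date` | date | ISO-8601; mandatory; ≤ discharge_date |
| `discharge_date` | date | ISO-8601; mandatory; drives period assignment |
| `ward_id` | string | optional |
| `age` | years, ≥ 0 | mandatory |
| `sex` | `male` / `female` | mandatory |
| `diabetes_type` | `type1` / `type2` / `none` | mandatory |
| `hba1c` | % | optional |
| `bmi` | kg/m² | optional; missing → GLP-1RA indeterminate |
| `egfr` | mL/min/1.73 m² | optional; missing → SGLT2i indeterminate |
| `serum_creatinine` | mg/dL | optional; used only by the disabled-by-default eGFR fall-back |
| `icd_codes` | list of ICD-10 codes | normalized to uppercase, no dot |
| `problem_text` | list of strings | free-text problem list |
| `medications` | list of strings | current medication names |
| `prednisone_regular` | boolean | regular prednisone use |
| `discharge_diagnosis_text` | string | free text, categorized by keywords |
| `period` | `pre` / `post` / empty | derivable from discharge_date |
| `physician_recommended` | boolean / empty | study outcome: recommendation in the discharge letter |

## Reason-code vocabulary

| code | meaning |
|---|---|
| `EXCL_AGE` | age below the screening minimum (default 18) |
| `EXCL_T1DM` | type 1 diabetes |
| `EXCL_NO_T2DM` | no type 2 diabetes diagnosis |
| `EXCL_ALREADY_TREATED` | already on an agent of this class |
| `CONTRA_EGFR_LT_30` | eGFR < 30 (SGLT2i) |
| `CONTRA_EGFR_LT_15` | eGFR < 15 (GLP-1RA) |
| `CONTRA_PANCREATITIS` | history of pancreatitis (GLP-1RA) |
| `CONTRA_PANCREATIC_CANCER` | pancreatic cancer (GLP-1RA) |
| `CONTRA_MTC` | medullary thyroid cancer (GLP-1RA) |
| `CONTRA_MEN2` | MEN2 (GLP-1RA; optional, off by default) |
| `MISSING_EGFR` | eGFR unavailable → indeterminate (SGLT2i) |
| `MISSING_BMI` | BMI unavailable → indeterminate (GLP-1RA) |
| `ELIG_CKD` | moderate–severe CKD (SGLT2i) |
| `ELIG_HF` | heart failure (SGLT2i) |
| `ELIG_ASCVD` | ASCVD (SGLT2i) |
| `ELIG_T2DM` | type 2 diabetes alone (SGLT2i permissive variant only) |
| `ELIG_BMI_GT_28` | BMI > 28 (GLP-1RA) |
| `ELIG_BMI_GT_25_WITH_CVD` | BMI > 25 with CVD (GLP-1RA) |
| `NO_QUALIFYING_CONDITION` | screened, no contraindication, no indication |

## Configuration files

* **Rule thresholds** (`RuleConfig.from_yaml`): any subset of the fields in
  `dischargerx.engine.RuleConfig`; omitted fields keep their defaults.
* **Period windows** (`PeriodWindows.from_yaml`):

  ```yaml
  pre_start: 2021-01-01
  pre_end: 2021-12-31
  post_start: 2023-04-01
  post_end: 2023-10-06
  ```

* **Code map** (`load_code_map`): `flags: {<flag>: {icd_prefixes: [...],
  keywords: [...]}}` plus `discharge_categories`; see
  `src/dischargerx/data/default_codemap.yaml` for the shipped default and its
  scope notes.
* **Simulator** (`SyntheticCohortConfig`): see `dischargerx.simulate`;
  defaults are the study-condition composition.
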