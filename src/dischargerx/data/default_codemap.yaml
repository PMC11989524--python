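# Default comorbidity dictionary: ICD-10 code prefixes (matched after
# normalization: uppercase, dot removed) and case-insensitive free-text
# keywords per flag.  The mapping is editable; every operation takes the map
# as a parameter, so a site can substitute its own dictionary.
#
# Scope choices documented here:
#   * "cancer" covers primary solid/hematologic malignancy (C00-C76, C81-C96)
#     and EXCLUDES in-situ disease (D00-D09) and non-melanoma skin cancer
#     (C44); metastatic disease is C77-C80.
#   * moderate-severe CKD is code-driven at stage >= 3b (N18.32 is stage 3a
#     in current coding and is deliberately not listed).
flags:
  ihd:
    icd_prefixes: [I20, I21, I22, I23, I24, I25]
    keywords: [ischemic heart disease, coronary artery disease, angina]
  cerebrovascular_disease:
    icd_prefixes: [I60, I61, I62, I63, I64, I65, I66, I67, I69, G45]
    keywords: [stroke, cva, tia, cerebrovascular]
  peripheral_vascular_disease:
    icd_prefixes: [I70, I71, I73, I74]
    keywords: [peripheral vascular disease, peripheral arterial disease, claudication]
  heart_failure:
    icd_prefixes: [I50, I110]
    keywords: [heart failure, chf]
  hypertension:
    icd_prefixes: [I10, I11, I12, I13, I15]
    keywords: [hypertension]
  dyslipidemia:
    icd_prefixes: [E78]
    keywords: [dyslipidemia, hyperlipidemia, hypercholesterolemia]
  cancer_non_metastatic:
    icd_prefixes: [C0, C1, C2, C30, C31, C32, C33, C34, C37, C38, C39,
                   C40, C41, C43, C45, C46, C47, C48, C49, C50, C51, C52,
                   C53, C54, C55, C56, C57, C58, C60, C61, C62, C63, C64,
                   C65, C66, C67, C68, C69, C70, C71, C72, C73, C74, C75,
                   C76, C81, C82, C83, C84, C85, C88, C90, C91, C92, C93,
                   C94, C95, C96]
    keywords: [carcinoma, lymphoma, leukemia, malignancy]
  cancer_metastatic:
    icd_prefixes: [C77, C78, C79, C80]
    keywords: [metastatic, metastases]
  liver_disease_mild:
    icd_prefixes: [K700, K701, K702, K703, K73, K760, B18]
    keywords: [fatty liver, chronic hepatitis, steatosis]
  liver_disease_moderate_severe:
    icd_prefixes: [K704, K72, K74, K766, K767, I85]
    keywords: [cirrhosis, hepatic failure, portal hypertension, esophageal varices]
  ckd_moderate_severe:
    icd_prefixes: [N184, N185]
    keywords: [ckd stage 4, ckd stage 5, stage 4 chronic kidney, stage 5 chronic kidney]
  t2dm_complication:
    icd_prefixes: [E112, E114, E115, E116]
    keywords: [diabetic nephropathy, diabetic neuropathy, diabetic foot, diabetic ulcer]
  pancreatitis_history:
    icd_prefixes: [K85, K860, K861]
    keywords: [pancreatitis]
  pancreatic_cancer:
    icd_prefixes: [C25]
    keywords: [pancreatic cancer, pancreatic carcinoma]
  medullary_thyroid_cancer:
    icd_prefixes: [C73]
    keywords: [medullary thyroid]
  men2:
    icd_prefixes: [E312]
    keywords: [men2, multiple endocrine neoplasia]
  dementia:
    icd_prefixes: [F00, F01, F02, F03, G30]
    keywords: [dementia, alzheimer]
  copd:
    icd_prefixes: [J44]
    keywords: [copd, chronic obstructive pulmonary]
  connective_tissue_disease:
    icd_prefixes: [M05, M06, M32, M33, M34, M353]
    keywords: [lupus, rheumatoid arthritis, systemic sclerosis, polymyositis]
  peptic_ulcer:
    icd_prefixes: [K25, K26, K27, K28]
    keywords: [peptic ulcer, gastric ulcer, duodenal ulcer]
  hemiplegia:
    icd_prefixes: [G81, G82]
    keywords: [hemiplegia, paraplegia, quadriplegia]
  aids:
    icd_prefixes: [B20, B21, B22, B23, B24]
    keywords: [aids, hiv]
  mi:
    icd_prefixes: [I21, I22, I252]
    keywords: [myocardial infarction]

# Discharge-diagnosis categorization keywords, applied to the free-text
# discharge diagnosis in this fixed priority order (first match wins):
# t2dm_complication > heart_failure > ihd > ischemic_stroke > ckd > other.
discharge_categories:
  t2dm_complication: [diabetic foot, hyperglycemia, hypoglycemia, diabetes complication,
                      diabetic ketoacidosis, hyperosmolar]
  heart_failure: [heart failure, chf, cardiac decompensation]
  ihd: [ischemic heart disease, myocardial infarction, angina, acute coronary,
        nstemi, stemi]
  ischemic_stroke: [ischemic stroke, stroke, cva]
  ckd: [chronic kidney disease, ckd, renal failure, kidney failure]
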