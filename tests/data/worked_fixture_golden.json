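{
 "W01_HF": {
  "sglt2i": {
   "status": "recommended",
   "reasons": [
    "ELIG_HF"
   ]
  },
  "glp1ra": {
   "status": "not_indicated",
   "reasons": [
    "NO_QUALIFYING_CONDITION"
   ]
  },
  "any_recommended": true
 },
 "W02_CKD": {
  "sglt2i": {
   "status": "recommended",
   "reasons": [
    "ELIG_CKD"
   ]
  },
  "glp1ra": {
   "status": "not_indicated",
   "reasons": [
    "NO_QUALIFYING_CONDITION"
   ]
  },
  "any_recommended": true
 },
 "W03_ASCVD_IHD": {
  "sglt2i": {
   "status": "recommended",
   "reasons": [
    "ELIG_ASCVD"
   ]
  },
  "glp1ra": {
   "status": "not_indicated",
   "reasons": [
    "NO_QUALIFYING_CONDITION"
   ]
  },
  "any_recommended": true
 },
 "W04_ASCVD_CVA": {
  "sglt2i": {
   "status": "recommended",
   "reasons": [
    "ELIG_ASCVD"
   ]
  },
  "glp1ra": {
   "status": "not_indicated",
   "reasons": [
    "NO_QUALIFYING_CONDITION"
   ]
  },
  "any_recommended": true
 },
 "W05_ASCVD_PVD": {
  "sglt2i": {
   "status": "recommended",
   "reasons": [
    "ELIG_ASCVD"
   ]
  },
  "glp1ra": {
   "status": "not_indicated",
   "reasons": [
    "NO_QUALIFYING_CONDITION"
   ]
  },
  "any_recommended": true
 },
 "W06_EGFR_25": {
  "sglt2i": {
   "status": "contraindicated",
   "reasons": [
    "CONTRA_EGFR_LT_30"
   ]
  },
  "glp1ra": {
   "status": "not_indicated",
   "reasons": [
    "NO_QUALIFYING_CONDITION"
   ]
  },
  "any_recommended": false
 },
 "W07_EGFR_30_BOUNDARY": {
  "sglt2i": {
   "status": "recommended",
   "reasons": [
    "ELIG_HF"
   ]
  },
  "glp1ra": {
   "status": "not_indicated",
   "reasons": [
    "NO_QUALIFYING_CONDITION"
   ]
  },
  "any_recommended": true
 },
 "W08_EGFR_MISSING": {
  "sglt2i": {
   "status": "indeterminate",
   "reasons": [
    "MISSING_EGFR"
   ]
  },
  "glp1ra": {
   "status": "not_indicated",
   "reasons": [
    "NO_QUALIFYING_CONDITION"
   ]
  },
  "any_recommended": false
 },
 "W09_BMI_29": {
  "sglt2i": {
   "status": "not_indicated",
   "reasons": [
    "NO_QUALIFYING_CONDITION"
   ]
  },
  "glp1ra": {
   "status": "recommended",
   "reasons": [
    "ELIG_BMI_GT_28"
   ]
  },
  "any_recommended": true
 },
 "W10_BMI_28_BOUNDARY": {
  "sglt2i": {
   "status": "not_indicated",
   "reasons": [
    "NO_QUALIFYING_CONDITION"
   ]
  },
  "glp1ra": {
   "status": "not_indicated",
   "reasons": [
    "NO_QUALIFYING_CONDITION"
   ]
  },
  "any_recommended": false
 },
 "W11_BMI_26_CVD": {
  "sglt2i": {
   "status": "recommended",
   "reasons": [
    "ELIG_ASCVD"
   ]
  },
  "glp1ra": {
   "status": "recommended",
   "reasons": [
    "ELIG_BMI_GT_25_WITH_CVD"
   ]
  },
  "any_recommended": true
 },
 "W12_BMI_25_BOUNDARY_CVD": {
  "sglt2i": {
   "status": "recommended",
   "reasons": [
    "ELIG_ASCVD"
   ]
  },
  "glp1ra": {
   "status": "not_indicated",
   "reasons": [
    "NO_QUALIFYING_CONDITION"
   ]
  },
  "any_recommended": true
 },
 "W13_BMI_26_HF_ONLY": {
  "sglt2i": {
   "status": "recommended",
   "reasons": [
    "ELIG_HF"
   ]
  },
  "glp1ra": {
   "status": "recommended",
   "reasons": [
    "ELIG_BMI_GT_25_WITH_CVD"
   ]
  },
  "any_recommended": true
 },
 "W14_BMI_MISSING": {
  "sglt2i": {
   "status": "recommended",
   "reasons": [
    "ELIG_HF"
   ]
  },
  "glp1ra": {
   "status": "indeterminate",
   "reasons": [
    "MISSING_BMI"
   ]
  },
  "any_recommended": true
 },
 "W15_PANCREATITIS": {
  "sglt2i": {
   "status": "not_indicated",
   "reasons": [
    "NO_QUALIFYING_CONDITION"
   ]
  },
  "glp1ra": {
   "status": "contraindicated",
   "reasons": [
    "CONTRA_PANCREATITIS"
   ]
  },
  "any_recommended": false
 },
 "W16_PANCREATIC_CA": {
  "sglt2i": {
   "status": "not_indicated",
   "reasons": [
    "NO_QUALIFYING_CONDITION"
   ]
  },
  "glp1ra": {
   "status": "contraindicated",
   "reasons": [
    "CONTRA_PANCREATIC_CANCER"
   ]
  },
  "any_recommended": false
 },
 "W17_MTC": {
  "sglt2i": {
   "status": "not_indicated",
   "reasons": [
    "NO_QUALIFYING_CONDITION"
   ]
  },
  "glp1ra": {
   "status": "contraindicated",
   "reasons": [
    "CONTRA_MTC"
   ]
  },
  "any_recommended": false
 },
 "W18_EGFR_10": {
  "sglt2i": {
   "status": "contraindicated",
   "reasons": [
    "CONTRA_EGFR_LT_30"
   ]
  },
  "glp1ra": {
   "status": "contraindicated",
   "reasons": [
    "CONTRA_EGFR_LT_15"
   ]
  },
  "any_recommended": false
 },
 "W19_EGFR_15_BOUNDARY": {
  "sglt2i": {
   "status": "contraindicated",
   "reasons": [
    "CONTRA_EGFR_LT_30"
   ]
  },
  "glp1ra": {
   "status": "recommended",
   "reasons": [
    "ELIG_BMI_GT_28"
   ]
  },
  "any_recommended": true
 },
 "W20_AGE_17": {
  "sglt2i": {
   "status": "excluded",
   "reasons": [
    "EXCL_AGE"
   ]
  },
  "glp1ra": {
   "status": "excluded",
   "reasons": [
    "EXCL_AGE"
   ]
  },
  "any_recommended": false
 },
 "W21_T1DM": {
  "sglt2i": {
   "status": "excluded",
   "reasons": [
    "EXCL_T1DM"
   ]
  },
  "glp1ra": {
   "status": "excluded",
   "reasons": [
    "EXCL_T1DM"
   ]
  },
  "any_recommended": false
 },
 "W22_NO_DM": {
  "sglt2i": {
   "status": "excluded",
   "reasons": [
    "EXCL_NO_T2DM"
   ]
  },
  "glp1ra": {
   "status": "excluded",
   "reasons": [
    "EXCL_NO_T2DM"
   ]
  },
  "any_recommended": false
 },
 "W23_ON_SGLT2I": {
  "sglt2i": {
   "status": "excluded",
   "reasons": [
    "EXCL_ALREADY_TREATED"
   ]
  },
  "glp1ra": {
   "status": "recommended",
   "reasons": [
    "ELIG_BMI_GT_28"
   ]
  },
  "any_recommended": true
 },
 "W24_ON_GLP1RA": {
  "sglt2i": {
   "status": "recommended",
   "reasons": [
    "ELIG_HF"
   ]
  },
  "glp1ra": {
   "status": "excluded",
   "reasons": [
    "EXCL_ALREADY_TREATED"
   ]
  },
  "any_recommended": true
 },
 "W25_NOT_INDICATED": {
  "sglt2i": {
   "status": "not_indicated",
   "reasons": [
    "NO_QUALIFYING_CONDITION"
   ]
  },
  "glp1ra": {
   "status": "not_indicated",
   "reasons": [
    "NO_QUALIFYING_CONDITION"
   ]
  },
  "any_recommended": false
 }
}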