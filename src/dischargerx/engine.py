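"""Rule engine recommending SGLT2i and/or GLP-1RA at hospital discharge.

The knowledge-based rules, per current ACC/ADA/ESC/EASD guidance as deployed
in the study setting:

* SGLT2i — eligible with type 2 diabetes AND (moderate-severe CKD, heart
  failure, or ASCVD); contraindicated when eGFR < 30 mL/min/1.73 m².
* GLP-1RA — eligible with type 2 diabetes AND (BMI > 28, or BMI > 25 with
  cardiovascular disease); contraindicated with a history of pancreatitis,
  pancreatic cancer, medullary thyroid cancer, or eGFR < 15 mL/min/1.73 m².
* HbA1c is deliberately disregarded: eligibility never consults it as long
  as the patient has type 2 diabetes.

Screening excludes patients under 18, without type 2 diabetes, or already
treated with an agent of the class under consideration.  All thresholds are
strict inequalities as printed (BMI = 28 or eGFR = 30 fall on the permissive
side), contraindications are evaluated before eligibility (a contraindicated
patient is never recommended), and a missing BMI/eGFR yields
``indeterminate`` — a fail-safe, never a recommendation.  Every decision
carries an ordered machine-readable reason trace.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, model_validator

from .comorbidity import CodeMap, ComorbidityProfile, default_code_map, map_codes
from .emr_model import Cohort, PatientRecord

__all__ = [
    "RuleConfig",
    "ClassDecision",
    "Recommendation",
    "DrugClass",
    "Status",
    "REASON_TEXT",
    "MED_CLASS_PATTERNS",
    "ANTIDIABETIC_PATTERNS",
    "medication_matches_class",
    "diabetes_medication_count",
    "screen_exclusions",
    "check_sglt2i",
    "check_glp1ra",
    "recommend",
    "eligible_cohort",
    "egfr_from_creatinine",
]

DrugClass = Literal["sglt2i", "glp1ra"]
Status = Literal[
    "recommended", "not_indicated", "contraindicated", "excluded", "indeterminate"
]

#: Reason-code vocabulary (machine code -> human-readable text).
REASON_TEXT = {
    # exclusions
    "EXCL_AGE": "age below the minimum for screening",
    "EXCL_T1DM": "type 1 diabetes",
    "EXCL_NO_T2DM": "no type 2 diabetes diagnosis",
    "EXCL_ALREADY_TREATED": "already treated with an agent of this class",
    # SGLT2i
    "CONTRA_EGFR_LT_30": "eGFR below 30 mL/min/1.73 m2",
    "MISSING_EGFR": "eGFR unavailable",
    "ELIG_CKD": "moderate-severe chronic kidney disease",
    "ELIG_HF": "heart failure",
    "ELIG_ASCVD": "atherosclerotic cardiovascular disease",
    "ELIG_T2DM": "type 2 diabetes (no additional indication required)",
    # GLP-1RA
    "CONTRA_PANCREATITIS": "history of pancreatitis",
    "CONTRA_PANCREATIC_CANCER": "pancreatic cancer",
    "CONTRA_MTC": "medullary thyroid cancer",
    "CONTRA_MEN2": "multiple endocrine neoplasia type 2",
    "CONTRA_EGFR_LT_15": "eGFR below 15 mL/min/1.73 m2",
    "MISSING_BMI": "BMI unavailable",
    "ELIG_BMI_GT_28": "BMI above 28 kg/m2",
    "ELIG_BMI_GT_25_WITH_CVD": "BMI above 25 kg/m2 with cardiovascular disease",
    # shared
    "NO_QUALIFYING_CONDITION": "no qualifying condition for this class",
}

#: Case-insensitive substring patterns identifying current treatment with
#: each class (molecule stems, brand names incl. combination products, and
#: ATC prefixes A10BK / A10BJ).
MED_CLASS_PATTERNS: dict[str, list[str]] = {
    "sglt2i": [
        "gliflozin",  # empagliflozin, dapagliflozin, ... incl. combinations
        "jardiance",
        "forxiga",
        "farxiga",
        "invokana",
        "steglatro",
        "xigduo",
        "synjardy",
        "glyxambi",
        "a10bk",
    ],
    "glp1ra": [
        "glutide",  # liraglutide, semaglutide, dulaglutide, albiglutide
        "exenatide",
        "lixisenatide",
        "ozempic",
        "rybelsus",
        "victoza",
        "saxenda",
        "wegovy",
        "trulicity",
        "byetta",
        "bydureon",
        "lyxumia",
        "xultophy",
        "a10bj",
    ],
}

#: Antidiabetic agents for the "taking >= 1 diabetes medication" stratifier.
ANTIDIABETIC_PATTERNS: list[str] = [
    "metformin",
    "insulin",
    "gliptin",  # DPP-4 inhibitors
    "glipizide",
    "gliclazide",
    "glimepiride",
    "glibenclamide",
    "glyburide",
    "repaglinide",
    "nateglinide",
    "acarbose",
    "pioglitazone",
    "rosiglitazone",
] + MED_CLASS_PATTERNS["sglt2i"] + MED_CLASS_PATTERNS["glp1ra"]


class RuleConfig(BaseModel):
    """Tunable thresholds of the decision rules (units in field names' docs).

    Defaults mirror the deployed algorithm: strict BMI cut-offs of 28 (solo
    pathway) and 25 (with CVD) kg/m²; eGFR contraindication cut-offs of 30
    (SGLT2i) and 15 (GLP-1RA) mL/min/1.73 m²; adults only.  The national
    formulary's HbA1c thresholds (7.0% for SGLT2i, 7.5% for GLP-1RA) are kept
    as documented constants but disregarded by default, matching the deployed
    rule set.
    """

    bmi_glp1_solo_threshold: float = 28.0
    bmi_glp1_cvd_threshold: float = 25.0
    egfr_sglt2i_contra: float = 30.0
    egfr_glp1ra_contra: float = 15.0
    min_age: float = 18.0
    obesity_threshold: float = 30.0
    cvd_definition: Literal["ascvd_only", "ascvd_plus_hf"] = "ascvd_plus_hf"
    hba1c_disregarded: bool = True
    #: formulary HbA1c thresholds (%); consulted only when hba1c_disregarded
    #: is False, in which case eligibility additionally requires HbA1c above
    #: the class threshold.
    hba1c_sglt2i_threshold: float = 7.0
    hba1c_glp1ra_threshold: float = 7.5
    sglt2i_requires_indication: bool = True
    men2_contraindicated: bool = False
    #: optional eGFR fall-back from serum creatinine (off by default; the
    #: deployed system reads eGFR directly from the EMR)
    egfr_fallback_from_creatinine: bool = False

    @model_validator(mode="after")
    def _check(self) -> "RuleConfig":
        for name in (
            "bmi_glp1_solo_threshold",
            "bmi_glp1_cvd_threshold",
            "egfr_sglt2i_contra",
            "egfr_glp1ra_contra",
            "min_age",
            "obesity_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.egfr_glp1ra_contra < self.egfr_sglt2i_contra:
            raise ValueError(
                "GLP-1RA eGFR cut-off must lie below the SGLT2i cut-off"
            )
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RuleConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


class ClassDecision(BaseModel):
    """Per-drug-class decision with an ordered reason trace."""

    drug_class: DrugClass
    status: Status
    reasons: list[str]

    @model_validator(mode="after")
    def _trace_complete(self) -> "ClassDecision":
        unknown = [r for r in self.reasons if r not in REASON_TEXT]
        if unknown:
            raise ValueError(f"unknown reason codes: {unknown}")
        if self.status == "recommended":
            if not any(r.startswith("ELIG_") for r in self.reasons):
                raise ValueError("recommended decision needs an ELIG_ reason")
            if any(r.startswith("CONTRA_") for r in self.reasons):
                raise ValueError("recommended decision cannot carry CONTRA_ reasons")
        elif not self.reasons:
            raise ValueError("non-recommended decision needs at least one reason")
        return self

    @property
    def reason_text(self) -> list[str]:
        return [REASON_TEXT[r] for r in self.reasons]


class Recommendation(BaseModel):
    """Composite output of the engine for one record."""

    sglt2i: ClassDecision
    glp1ra: ClassDecision

    @property
    def any_recommended(self) -> bool:
        return (
            self.sglt2i.status == "recommended"
            or self.glp1ra.status == "recommended"
        )


def egfr_from_creatinine(
    creatinine_mg_dl: float, age: float, sex: str
) -> float:
    """Estimated GFR from serum creatinine (CKD-EPI 2021, race-free).

    Provided as optional plumbing; disabled by default in :class:`RuleConfig`
    since the deployed system reads eGFR directly from the EMR.
    """
    kappa = 0.7 if sex == "female" else 0.9
    alpha = -0.241 if sex == "female" else -0.302
    ratio = creatinine_mg_dl / kappa
    egfr = (
        142.0
        * min(ratio, 1.0) ** alpha
        * max(ratio, 1.0) ** -1.200
        * 0.9938**age
    )
    if sex == "female":
        egfr *= 1.012
    return egfr


def _effective_egfr(record: PatientRecord, config: RuleConfig) -> Optional[float]:
    if record.egfr is not None:
        return record.egfr
    if (
        config.egfr_fallback_from_creatinine
        and record.serum_creatinine is not None
        and record.serum_creatinine > 0
    ):
        return egfr_from_creatinine(record.serum_creatinine, record.age, record.sex)
    return None


def medication_matches_class(medication: str, drug_class: str) -> bool:
    """Class-level (not molecule-level) match of one medication string."""
    low = medication.lower()
    return any(pat in low for pat in MED_CLASS_PATTERNS[drug_class])


def diabetes_medication_count(medications: list[str]) -> int:
    """Number of medication strings matching any antidiabetic pattern."""
    return sum(
        1
        for m in medications
        if any(pat in m.lower() for pat in ANTIDIABETIC_PATTERNS)
    )


def screen_exclusions(
    record: PatientRecord,
    drug_class: DrugClass,
    config: Optional[RuleConfig] = None,
) -> list[str]:
    """Population screening for one drug class; empty list means 'passes'.

    Excludes minors, patients without type 2 diabetes (type 1 reported
    specifically), and patients already treated with an agent of the class
    under consideration (class-level match, per class).
    """
    cfg = config if config is not None else RuleConfig()
    reasons: list[str] = []
    if record.age < cfg.min_age:
        reasons.append("EXCL_AGE")
    if record.diabetes_type == "type1":
        reasons.append("EXCL_T1DM")
    elif record.diabetes_type != "type2":
        reasons.append("EXCL_NO_T2DM")
    if any(medication_matches_class(m, drug_class) for m in record.medications):
        reasons.append("EXCL_ALREADY_TREATED")
    return reasons


def _hba1c_blocks(record: PatientRecord, threshold: float, config: RuleConfig) -> bool:
    # only consulted when the formulary HbA1c gate is switched back on
    if config.hba1c_disregarded:
        return False
    return record.hba1c is None or not record.hba1c > threshold


def check_sglt2i(
    record: PatientRecord,
    profile: ComorbidityProfile,
    config: Optional[RuleConfig] = None,
) -> ClassDecision:
    """SGLT2i rule: qualifying condition is CKD, HF, or ASCVD.

    Assumes exclusion screening already passed.  Contraindication (eGFR
    strictly below the cut-off) dominates; a missing eGFR is indeterminate.
    """
    cfg = config if config is not None else RuleConfig()
    egfr = _effective_egfr(record, cfg)
    if egfr is not None and egfr < cfg.egfr_sglt2i_contra:
        return ClassDecision(
            drug_class="sglt2i", status="contraindicated", reasons=["CONTRA_EGFR_LT_30"]
        )
    if egfr is None:
        return ClassDecision(
            drug_class="sglt2i", status="indeterminate", reasons=["MISSING_EGFR"]
        )
    if _hba1c_blocks(record, cfg.hba1c_sglt2i_threshold, cfg):
        return ClassDecision(
            drug_class="sglt2i",
            status="not_indicated",
            reasons=["NO_QUALIFYING_CONDITION"],
        )
    reasons = []
    if profile.ckd_moderate_severe:
        reasons.append("ELIG_CKD")
    if profile.heart_failure:
        reasons.append("ELIG_HF")
    if profile.ascvd:
        reasons.append("ELIG_ASCVD")
    if reasons:
        return ClassDecision(drug_class="sglt2i", status="recommended", reasons=reasons)
    if not cfg.sglt2i_requires_indication:
        return ClassDecision(
            drug_class="sglt2i", status="recommended", reasons=["ELIG_T2DM"]
        )
    return ClassDecision(
        drug_class="sglt2i", status="not_indicated", reasons=["NO_QUALIFYING_CONDITION"]
    )


def check_glp1ra(
    record: PatientRecord,
    profile: ComorbidityProfile,
    config: Optional[RuleConfig] = None,
) -> ClassDecision:
    """GLP-1RA rule: BMI > 28 alone, or BMI > 25 with cardiovascular disease.

    Assumes exclusion screening already passed.  All applicable
    contraindications are reported together and dominate eligibility; a
    missing BMI is indeterminate.
    """
    cfg = config if config is not None else RuleConfig()
    contra = []
    if profile.pancreatitis_history:
        contra.append("CONTRA_PANCREATITIS")
    if profile.pancreatic_cancer:
        contra.append("CONTRA_PANCREATIC_CANCER")
    if profile.medullary_thyroid_cancer:
        contra.append("CONTRA_MTC")
    if cfg.men2_contraindicated and profile.men2:
        contra.append("CONTRA_MEN2")
    egfr = _effective_egfr(record, cfg)
    if egfr is not None and egfr < cfg.egfr_glp1ra_contra:
        contra.append("CONTRA_EGFR_LT_15")
    if contra:
        return ClassDecision(
            drug_class="glp1ra", status="contraindicated", reasons=contra
        )
    if record.bmi is None:
        return ClassDecision(
            drug_class="glp1ra", status="indeterminate", reasons=["MISSING_BMI"]
        )
    if _hba1c_blocks(record, cfg.hba1c_glp1ra_threshold, cfg):
        return ClassDecision(
            drug_class="glp1ra",
            status="not_indicated",
            reasons=["NO_QUALIFYING_CONDITION"],
        )
    if record.bmi > cfg.bmi_glp1_solo_threshold:
        return ClassDecision(
            drug_class="glp1ra", status="recommended", reasons=["ELIG_BMI_GT_28"]
        )
    has_cvd = (
        profile.ascvd
        if cfg.cvd_definition == "ascvd_only"
        else profile.cvd_any
    )
    if record.bmi > cfg.bmi_glp1_cvd_threshold and has_cvd:
        return ClassDecision(
            drug_class="glp1ra",
            status="recommended",
            reasons=["ELIG_BMI_GT_25_WITH_CVD"],
        )
    return ClassDecision(
        drug_class="glp1ra", status="not_indicated", reasons=["NO_QUALIFYING_CONDITION"]
    )


def recommend(
    record: PatientRecord,
    code_map: Optional[CodeMap] = None,
    config: Optional[RuleConfig] = None,
    profile: Optional[ComorbidityProfile] = None,
) -> Recommendation:
    """Full per-record decision: comorbidity mapping, screening, both rules.

    Deterministic, with the complete reason trace retained.  ``profile`` can
    be passed to skip re-mapping when the caller already derived it.
    """
    cmap = code_map if code_map is not None else default_code_map()
    cfg = config if config is not None else RuleConfig()
    prof = (
        profile
        if profile is not None
        else map_codes(record.icd_codes, record.problem_text, record.bmi, cmap)
    )
    decisions = {}
    for drug_class, checker in (("sglt2i", check_sglt2i), ("glp1ra", check_glp1ra)):
        excl = screen_exclusions(record, drug_class, cfg)  # type: ignore[arg-type]
        if excl:
            decisions[drug_class] = ClassDecision(
                drug_class=drug_class, status="excluded", reasons=excl
            )
        else:
            decisions[drug_class] = checker(record, prof, cfg)
    return Recommendation(sglt2i=decisions["sglt2i"], glp1ra=decisions["glp1ra"])


def eligible_cohort(
    cohort: Cohort,
    code_map: Optional[CodeMap] = None,
    config: Optional[RuleConfig] = None,
) -> tuple[Cohort, list[Recommendation], dict]:
    """Filter a deduplicated cohort to records with any recommendation.

    Returns the surviving records (input order preserved), their attached
    :class:`Recommendation` objects, and a disposition summary counting, for
    each drug class, the reason codes observed among records that received no
    recommendation at all.
    """
    cmap = code_map if code_map is not None else default_code_map()
    cfg = config if config is not None else RuleConfig()
    kept_records: list[PatientRecord] = []
    kept_recs: list[Recommendation] = []
    by_reason: dict[str, Counter] = {"sglt2i": Counter(), "glp1ra": Counter()}
    for rec in cohort:
        r = recommend(rec, cmap, cfg)
        if r.any_recommended:
            kept_records.append(rec)
            kept_recs.append(r)
        else:
            by_reason["sglt2i"].update(r.sglt2i.reasons)
            by_reason["glp1ra"].update(r.glp1ra.reasons)
    disposition = {
        "n_input": len(cohort),
        "n_eligible": len(kept_records),
        "by_reason": {cls: dict(cnt) for cls, cnt in by_reason.items()},
    }
    meta = dict(cohort.metadata)
    meta["disposition"] = disposition
    return Cohort(records=kept_records, metadata=meta), kept_recs, disposition
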