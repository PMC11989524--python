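"""Comorbidity extraction from ICD-10 codes, free text, and measurements.

A :class:`ComorbidityProfile` is a set of boolean condition flags derived
deterministically from a patient's diagnosis codes (prefix match after
normalization), problem-list strings (case-insensitive substring of curated
keywords — no NLP), and BMI.  Composites follow the study definitions:

* ASCVD = ischemic heart disease OR cerebrovascular disease OR peripheral
  vascular disease;
* obesity = BMI present AND BMI > 30 kg/m²;
* type 2 diabetes complication = nephropathy, neuropathy, diabetic foot, or
  amputation due to diabetic foot.

The module also categorizes the free-text discharge diagnosis into one of
six mutually exclusive buckets and computes the Charlson comorbidity index
(original 1987 weights, no age adjustment).
"""

from __future__ import annotations

import logging
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .emr_model import ICD10_PATTERN, normalize_icd

__all__ = [
    "ComorbidityProfile",
    "CodeMap",
    "CodeMapEntry",
    "FLAG_NAMES",
    "DISCHARGE_CATEGORIES",
    "default_code_map",
    "load_code_map",
    "map_codes",
    "classify_discharge",
    "compute_cci",
]

logger = logging.getLogger(__name__)

#: Base (non-derived) flags; every CodeMap must cover all of them.
FLAG_NAMES = [
    "ihd",
    "cerebrovascular_disease",
    "peripheral_vascular_disease",
    "heart_failure",
    "hypertension",
    "dyslipidemia",
    "cancer_non_metastatic",
    "cancer_metastatic",
    "liver_disease_mild",
    "liver_disease_moderate_severe",
    "ckd_moderate_severe",
    "t2dm_complication",
    "pancreatitis_history",
    "pancreatic_cancer",
    "medullary_thyroid_cancer",
    "men2",
    "dementia",
    "copd",
    "connective_tissue_disease",
    "peptic_ulcer",
    "hemiplegia",
    "aids",
    "mi",
]

#: Discharge-diagnosis buckets in match priority order; "other" is fallback.
DISCHARGE_CATEGORIES = [
    "t2dm_complication",
    "heart_failure",
    "ihd",
    "ischemic_stroke",
    "ckd",
    "other",
]


class ComorbidityProfile(BaseModel):
    """Boolean comorbidity flags plus derived composites."""

    ihd: bool = False
    cerebrovascular_disease: bool = False
    peripheral_vascular_disease: bool = False
    heart_failure: bool = False
    hypertension: bool = False
    dyslipidemia: bool = False
    cancer_non_metastatic: bool = False
    cancer_metastatic: bool = False
    liver_disease_mild: bool = False
    liver_disease_moderate_severe: bool = False
    ckd_moderate_severe: bool = False
    t2dm_complication: bool = False
    pancreatitis_history: bool = False
    pancreatic_cancer: bool = False
    medullary_thyroid_cancer: bool = False
    men2: bool = False
    dementia: bool = False
    copd: bool = False
    connective_tissue_disease: bool = False
    peptic_ulcer: bool = False
    hemiplegia: bool = False
    aids: bool = False
    mi: bool = False
    #: obesity is the only stored derived flag (it needs BMI, which the
    #: profile does not carry); set by :func:`map_codes`.
    obesity: bool = False

    @model_validator(mode="after")
    def _severity_exclusive(self) -> "ComorbidityProfile":
        # moderate-severe liver disease supersedes mild
        if self.liver_disease_moderate_severe and self.liver_disease_mild:
            object.__setattr__(self, "liver_disease_mild", False)
        return self

    @property
    def ascvd(self) -> bool:
        """Atherosclerotic CVD composite (always consistent with components)."""
        return (
            self.ihd
            or self.cerebrovascular_disease
            or self.peripheral_vascular_disease
        )

    @property
    def cvd_any(self) -> bool:
        """Broad cardiovascular disease: ASCVD or heart failure."""
        return self.ascvd or self.heart_failure

    @property
    def cancer_any(self) -> bool:
        return self.cancer_non_metastatic or self.cancer_metastatic

    @property
    def liver_disease_any(self) -> bool:
        return self.liver_disease_mild or self.liver_disease_moderate_severe


class CodeMapEntry(BaseModel):
    icd_prefixes: list[str] = Field(default_factory=list)
    keywords: list[str] = Field(default_factory=list)

    @field_validator("icd_prefixes", mode="after")
    @classmethod
    def _norm_prefixes(cls, prefixes: list[str]) -> list[str]:
        return [normalize_icd(p) for p in prefixes]

    @field_validator("keywords", mode="after")
    @classmethod
    def _lower_keywords(cls, kws: list[str]) -> list[str]:
        return [k.strip().lower() for k in kws]


class CodeMap(BaseModel):
    """Editable dictionary driving code/text extraction.

    ``flags`` maps every profile flag to ICD-10 prefixes and free-text
    keywords; ``discharge_categories`` maps each non-fallback discharge
    bucket to its keywords.
    """

    flags: dict[str, CodeMapEntry]
    discharge_categories: dict[str, list[str]] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _complete(self) -> "CodeMap":
        missing = [f for f in FLAG_NAMES if f not in self.flags]
        if missing:
            raise ValueError(f"CodeMap missing flags: {missing}")
        unknown = [f for f in self.flags if f not in FLAG_NAMES]
        if unknown:
            raise ValueError(f"CodeMap has unknown flags: {unknown}")
        bad = [c for c in self.discharge_categories if c not in DISCHARGE_CATEGORIES]
        if bad:
            raise ValueError(f"unknown discharge categories: {bad}")
        self.discharge_categories = {
            cat: [k.strip().lower() for k in kws]
            for cat, kws in self.discharge_categories.items()
        }
        return self


def load_code_map(path: str | Path) -> CodeMap:
    """Load a CodeMap from its YAML schema (flag -> prefixes/keywords)."""
    with open(path, "r", encoding="utf-8") as fh:
        return CodeMap.model_validate(yaml.safe_load(fh))


@lru_cache(maxsize=1)
def default_code_map() -> CodeMap:
    """The code map shipped with the package (standard ICD-10 prefixes)."""
    text = (
        resources.files("dischargerx.data")
        .joinpath("default_codemap.yaml")
        .read_text(encoding="utf-8")
    )
    return CodeMap.model_validate(yaml.safe_load(text))


def map_codes(
    icd_codes: list[str],
    problem_text: list[str],
    bmi: Optional[float],
    code_map: Optional[CodeMap] = None,
) -> ComorbidityProfile:
    """Derive a comorbidity profile from codes, free text, and BMI.

    A flag is true iff any normalized code starts with one of its ICD
    prefixes OR any problem string contains one of its keywords
    (case-insensitive).  Matching is order-independent and idempotent with
    respect to duplicate codes.  Codes that do not normalize to the ICD-10
    lexical shape are logged and ignored.
    """
    cmap = code_map if code_map is not None else default_code_map()
    codes = []
    for raw in icd_codes:
        norm = normalize_icd(raw)
        if ICD10_PATTERN.match(norm):
            codes.append(norm)
        else:
            logger.warning("ignoring unnormalizable ICD code %r", raw)
    texts = [t.lower() for t in problem_text]

    values: dict[str, bool] = {}
    for flag, entry in cmap.flags.items():
        hit = any(c.startswith(p) for c in codes for p in entry.icd_prefixes)
        if not hit and entry.keywords:
            hit = any(kw in t for t in texts for kw in entry.keywords)
        values[flag] = hit
    values["obesity"] = bmi is not None and bmi > 30.0
    return ComorbidityProfile(**values)


def classify_discharge(
    discharge_diagnosis_text: str, code_map: Optional[CodeMap] = None
) -> str:
    """Categorize the discharge diagnosis text.

    The first matching category in the fixed priority order
    t2dm_complication > heart_failure > ihd > ischemic_stroke > ckd wins;
    anything else (including empty text) is ``other``.
    """
    cmap = code_map if code_map is not None else default_code_map()
    text = discharge_diagnosis_text.lower()
    for cat in DISCHARGE_CATEGORIES[:-1]:
        for kw in cmap.discharge_categories.get(cat, []):
            if kw in text:
                return cat
    return "other"


def compute_cci(profile: ComorbidityProfile, has_diabetes: bool) -> int:
    """Charlson comorbidity index with the original weights.

    Within a category only the highest severity counts: metastatic disease
    supersedes non-metastatic cancer, moderate-severe supersedes mild liver
    disease, and diabetes with end-organ damage (weight 2) supersedes
    uncomplicated diabetes (weight 1).  No age adjustment.
    """
    score = 0
    for flag in (
        "mi",
        "heart_failure",
        "peripheral_vascular_disease",
        "cerebrovascular_disease",
        "dementia",
        "copd",
        "connective_tissue_disease",
        "peptic_ulcer",
    ):
        score += 1 if getattr(profile, flag) else 0
    if profile.liver_disease_moderate_severe:
        score += 3
    elif profile.liver_disease_mild:
        score += 1
    if has_diabetes:
        score += 2 if profile.t2dm_complication else 1
    score += 2 if profile.hemiplegia else 0
    score += 2 if profile.ckd_moderate_severe else 0
    if profile.cancer_metastatic:
        score += 6
    elif profile.cancer_non_metastatic:
        score += 2
    score += 6 if profile.aids else 0
    return score
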