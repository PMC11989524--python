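"""Independent reference implementations used only as test oracles.

These are deliberately written as flat truth tables / brute-force
enumerations, structurally unlike the package code they check.
"""

from __future__ import annotations

import math
from itertools import permutations


def reference_decision(
    *,
    diabetes_type: str = "type2",
    age: float = 70.0,
    on_sglt2i: bool = False,
    on_glp1ra: bool = False,
    bmi: float | None = None,
    egfr: float | None = None,
    ckd: bool = False,
    hf: bool = False,
    ihd: bool = False,
    cva: bool = False,
    pvd: bool = False,
    pancreatitis: bool = False,
    pancreatic_cancer: bool = False,
    mtc: bool = False,
    cvd_includes_hf: bool = True,
) -> dict:
    """Brute-force decision table for both drug classes."""
    ascvd = ihd or cva or pvd
    out: dict = {}

    for cls in ("sglt2i", "glp1ra"):
        excl = []
        if age < 18:
            excl.append("EXCL_AGE")
        if diabetes_type == "type1":
            excl.append("EXCL_T1DM")
        elif diabetes_type != "type2":
            excl.append("EXCL_NO_T2DM")
        treated = on_sglt2i if cls == "sglt2i" else on_glp1ra
        if treated:
            excl.append("EXCL_ALREADY_TREATED")
        if excl:
            out[cls] = ("excluded", excl)
            continue

        if cls == "sglt2i":
            if egfr is not None and egfr < 30:
                out[cls] = ("contraindicated", ["CONTRA_EGFR_LT_30"])
            elif egfr is None:
                out[cls] = ("indeterminate", ["MISSING_EGFR"])
            else:
                reasons = []
                if ckd:
                    reasons.append("ELIG_CKD")
                if hf:
                    reasons.append("ELIG_HF")
                if ascvd:
                    reasons.append("ELIG_ASCVD")
                out[cls] = (
                    ("recommended", reasons)
                    if reasons
                    else ("not_indicated", ["NO_QUALIFYING_CONDITION"])
                )
        else:
            contra = []
            if pancreatitis:
                contra.append("CONTRA_PANCREATITIS")
            if pancreatic_cancer:
                contra.append("CONTRA_PANCREATIC_CANCER")
            if mtc:
                contra.append("CONTRA_MTC")
            if egfr is not None and egfr < 15:
                contra.append("CONTRA_EGFR_LT_15")
            if contra:
                out[cls] = ("contraindicated", contra)
            elif bmi is None:
                out[cls] = ("indeterminate", ["MISSING_BMI"])
            elif bmi > 28:
                out[cls] = ("recommended", ["ELIG_BMI_GT_28"])
            elif bmi > 25 and (ascvd or (hf and cvd_includes_hf)):
                out[cls] = ("recommended", ["ELIG_BMI_GT_25_WITH_CVD"])
            else:
                out[cls] = ("not_indicated", ["NO_QUALIFYING_CONDITION"])

    out["any_recommended"] = (
        out["sglt2i"][0] == "recommended" or out["glp1ra"][0] == "recommended"
    )
    return out


def crude_or_by_hand(a: int, b: int, c: int, d: int, z: float = 1.959963984540054):
    """Hand evaluation of the cross-product OR and Wald interval."""
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(orr) - z * se)
    hi = math.exp(math.log(orr) + z * se)
    return orr, lo, hi


def _log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by explicit hypergeometric enumeration.

    Sums the probabilities of all same-margin tables whose probability does
    not exceed the observed table's (within a 1+1e-7 tolerance factor).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_prob(x: int) -> float:
        return (
            _log_binom(r1, x)
            + _log_binom(r2, c1 - x)
            - _log_binom(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = math.exp(log_prob(a))
    total = 0.0
    for x in range(lo, hi + 1):
        p = math.exp(log_prob(x))
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


def dedupe_brute_force(records):
    """Group-by/min reference for first-hospitalization dedup."""
    groups: dict = {}
    for rec in records:
        groups.setdefault((rec.patient_id, rec.period), []).append(rec)
    keep = set()
    for recs in groups.values():
        earliest = min(r.admission_date for r in recs)
        first = next(r for r in recs if r.admission_date == earliest)
        keep.add(id(first))
    return [r for r in records if id(r) in keep]
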