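"""Decision-engine rules, reason traces, and oracle equivalence."""

import datetime as dt
import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dischargerx.comorbidity import map_codes
from dischargerx.emr_model import Cohort, PatientRecord
from dischargerx.engine import (
    RuleConfig,
    check_glp1ra,
    check_sglt2i,
    eligible_cohort,
    recommend,
    screen_exclusions,
)

from oracles import reference_decision

#: flag -> (ICD code realizing it, oracle keyword)
FLAG_CODES = {
    "ckd": "N18.4",
    "hf": "I50",
    "ihd": "I25.1",
    "pancreatitis": "K85",
    "pancreatic_cancer": "C25",
    "mtc": None,  # via free text
}

BMI_GRID = [24.0, 25.0, 25.1, 28.0, 28.1, 35.0, None]
EGFR_GRID = [10.0, 14.9, 15.0, 29.9, 30.0, 60.0, None]


def make_record(**kw):
    defaults = dict(
        patient_id="P1",
        admission_date=dt.date(2021, 2, 1),
        discharge_date=dt.date(2021, 2, 5),
        age=70.0,
        sex="female",
        diabetes_type="type2",
        bmi=24.0,
        egfr=60.0,
    )
    defaults.update(kw)
    return PatientRecord(**defaults)


def record_for(flags: dict, bmi, egfr, diabetes_type="type2", age=70.0, meds=()):
    codes = [FLAG_CODES[f] for f, on in flags.items() if on and FLAG_CODES[f]]
    text = ["medullary thyroid carcinoma"] if flags.get("mtc") else []
    return make_record(
        diabetes_type=diabetes_type,
        age=age,
        bmi=bmi,
        egfr=egfr,
        icd_codes=codes,
        problem_text=text,
        medications=list(meds),
    )


class TestExclusions:
    def test_minor_excluded(self):
        rec = make_record(age=17.0)
        assert screen_exclusions(rec, "sglt2i") == ["EXCL_AGE"]

    def test_type1_excluded(self):
        rec = make_record(diabetes_type="type1")
        assert screen_exclusions(rec, "glp1ra") == ["EXCL_T1DM"]

    def test_no_diabetes_excluded(self):
        rec = make_record(diabetes_type="none")
        assert screen_exclusions(rec, "sglt2i") == ["EXCL_NO_T2DM"]

    def test_already_treated_is_per_class(self):
        rec = make_record(medications=["Empagliflozin 10mg"])
        assert screen_exclusions(rec, "sglt2i") == ["EXCL_ALREADY_TREATED"]
        assert screen_exclusions(rec, "glp1ra") == []

    def test_combination_product_counts(self):
        rec = make_record(medications=["empagliflozin/metformin"])
        assert "EXCL_ALREADY_TREATED" in screen_exclusions(rec, "sglt2i")


class TestSglt2iRule:
    def test_hf_with_adequate_egfr_recommended(self, code_map):
        rec = record_for({"hf": True}, bmi=24.0, egfr=60.0)
        prof = map_codes(rec.icd_codes, rec.problem_text, rec.bmi, code_map)
        decision = check_sglt2i(rec, prof)
        assert decision.status == "recommended"
        assert decision.reasons == ["ELIG_HF"]

    @pytest.mark.parametrize(
        "egfr, status",
        [(25.0, "contraindicated"), (29.9, "contraindicated"),
         (30.0, "recommended"), (None, "indeterminate")],
    )
    def test_egfr_gate_strict_inequality(self, code_map, egfr, status):
        rec = record_for({"hf": True}, bmi=24.0, egfr=egfr)
        prof = map_codes(rec.icd_codes, rec.problem_text, rec.bmi, code_map)
        assert check_sglt2i(rec, prof).status == status

    def test_hba1c_ignored_when_disregarded(self, code_map):
        rec = record_for({}, bmi=24.0, egfr=80.0)
        rec = rec.model_copy(update={"hba1c": 9.0})
        prof = map_codes(rec.icd_codes, rec.problem_text, rec.bmi, code_map)
        decision = check_sglt2i(rec, prof)
        assert decision.status == "not_indicated"
        assert decision.reasons == ["NO_QUALIFYING_CONDITION"]

    def test_all_applicable_eligibility_reasons_reported(self, code_map):
        rec = record_for({"hf": True, "ckd": True, "ihd": True}, bmi=24.0, egfr=60.0)
        prof = map_codes(rec.icd_codes, rec.problem_text, rec.bmi, code_map)
        assert check_sglt2i(rec, prof).reasons == ["ELIG_CKD", "ELIG_HF", "ELIG_ASCVD"]


class TestGlp1raRule:
    @pytest.mark.parametrize(
        "bmi, flags, status, reason",
        [
            (29.0, {}, "recommended", "ELIG_BMI_GT_28"),
            (28.0, {}, "not_indicated", "NO_QUALIFYING_CONDITION"),
            (26.0, {"ihd": True}, "recommended", "ELIG_BMI_GT_25_WITH_CVD"),
            (25.0, {"ihd": True}, "not_indicated", "NO_QUALIFYING_CONDITION"),
            (None, {}, "indeterminate", "MISSING_BMI"),
        ],
    )
    def test_bmi_pathways_strict_inequalities(self, code_map, bmi, flags, status, reason):
        rec = record_for(flags, bmi=bmi, egfr=60.0)
        prof = map_codes(rec.icd_codes, rec.problem_text, rec.bmi, code_map)
        decision = check_glp1ra(rec, prof)
        assert decision.status == status
        assert decision.reasons == [reason]

    def test_pancreatitis_contraindication_dominates_high_bmi(self, code_map):
        rec = record_for({"pancreatitis": True}, bmi=32.0, egfr=60.0)
        prof = map_codes(rec.icd_codes, rec.problem_text, rec.bmi, code_map)
        decision = check_glp1ra(rec, prof)
        assert decision.status == "contraindicated"
        assert decision.reasons == ["CONTRA_PANCREATITIS"]

    def test_low_egfr_contraindication_precedes_eligibility(self, code_map):
        rec = record_for({}, bmi=35.0, egfr=10.0)
        prof = map_codes(rec.icd_codes, rec.problem_text, rec.bmi, code_map)
        decision = check_glp1ra(rec, prof)
        assert decision.status == "contraindicated"
        assert decision.reasons == ["CONTRA_EGFR_LT_15"]

    def test_hf_counts_as_cvd_by_default_but_not_under_ascvd_only(self, code_map):
        rec = record_for({"hf": True}, bmi=26.0, egfr=60.0)
        prof = map_codes(rec.icd_codes, rec.problem_text, rec.bmi, code_map)
        assert check_glp1ra(rec, prof).status == "recommended"
        ascvd_only = RuleConfig(cvd_definition="ascvd_only")
        assert check_glp1ra(rec, prof, ascvd_only).status == "not_indicated"


class TestRecommendComposition:
    def test_hf_low_bmi(self, code_map, rules):
        rec = record_for({"hf": True}, bmi=24.0, egfr=50.0)
        r = recommend(rec, code_map, rules)
        assert r.sglt2i.status == "recommended"
        assert r.glp1ra.status == "not_indicated"
        assert r.any_recommended

    def test_type1_both_excluded(self, code_map, rules):
        rec = record_for({"hf": True}, bmi=32.0, egfr=50.0, diabetes_type="type1")
        r = recommend(rec, code_map, rules)
        assert r.sglt2i.status == "excluded" == r.glp1ra.status
        assert not r.any_recommended

    def test_split_decision_low_egfr_high_bmi(self, code_map, rules):
        rec = record_for({"hf": True}, bmi=31.0, egfr=25.0)
        r = recommend(rec, code_map, rules)
        assert r.sglt2i.status == "contraindicated"
        assert r.glp1ra.status == "recommended"

    def test_determinism_including_reason_order(self, code_map, rules):
        rec = record_for({"hf": True, "ckd": True, "ihd": True}, bmi=26.0, egfr=40.0)
        runs = [recommend(rec, code_map, rules) for _ in range(3)]
        assert runs[0] == runs[1] == runs[2]


class TestEligibleCohort:
    def test_filter_semantics(self, code_map, rules):
        eligible = [record_for({"hf": True}, bmi=24.0, egfr=60.0) for _ in range(4)]
        ineligible = [record_for({}, bmi=24.0, egfr=60.0) for _ in range(6)]
        cohort = Cohort(records=eligible + ineligible)
        kept, recs, disposition = eligible_cohort(cohort, code_map, rules)
        assert len(kept) == 4 == len(recs)
        assert all(r.any_recommended for r in recs)
        assert disposition["n_input"] == 10 and disposition["n_eligible"] == 4

    def test_all_type1_disposition(self, code_map, rules):
        cohort = Cohort(
            records=[record_for({"hf": True}, 32.0, 60.0, diabetes_type="type1")
                     for _ in range(10)]
        )
        kept, _, disposition = eligible_cohort(cohort, code_map, rules)
        assert len(kept) == 0
        assert disposition["by_reason"]["sglt2i"]["EXCL_T1DM"] == 10
        assert disposition["by_reason"]["glp1ra"]["EXCL_T1DM"] == 10


# --- property tests over random records -------------------------------------

record_strategy = st.builds(
    record_for,
    flags=st.fixed_dictionaries(
        {name: st.booleans() for name in FLAG_CODES}
    ),
    bmi=st.sampled_from(BMI_GRID),
    egfr=st.sampled_from(EGFR_GRID),
    diabetes_type=st.sampled_from(["type1", "type2", "none"]),
    age=st.sampled_from([17.0, 18.0, 45.0, 75.0, 92.0]),
)


@settings(max_examples=150, deadline=None)
@given(rec=record_strategy, hba1c=st.one_of(st.none(), st.floats(4.0, 15.0)))
def test_hba1c_never_changes_any_decision(rec, hba1c):
    base = recommend(rec)
    perturbed = recommend(rec.model_copy(update={"hba1c": hba1c}))
    assert base == perturbed


@settings(max_examples=150, deadline=None)
@given(
    rec=record_strategy,
    bump=st.floats(0.0, 20.0, allow_nan=False),
)
def test_glp1ra_monotone_in_bmi(rec, bump):
    if rec.bmi is None:
        return
    lo = recommend(rec)
    hi = recommend(rec.model_copy(update={"bmi": rec.bmi + bump}))
    if lo.glp1ra.status == "recommended":
        assert hi.glp1ra.status == "recommended"


@settings(max_examples=150, deadline=None)
@given(rec=record_strategy)
def test_contraindication_flip_never_creates_recommendation(rec):
    base = recommend(rec)
    worse = recommend(
        rec.model_copy(update={"icd_codes": rec.icd_codes + ["K85"]})
    )
    if base.glp1ra.status != "recommended":
        assert worse.glp1ra.status != "recommended"


@settings(max_examples=150, deadline=None)
@given(rec=record_strategy)
def test_trace_completeness(rec):
    r = recommend(rec)
    for decision in (r.sglt2i, r.glp1ra):
        if decision.status != "recommended":
            assert len(decision.reasons) >= 1
        else:
            assert any(code.startswith("ELIG_") for code in decision.reasons)
            assert not any(code.startswith("CONTRA_") for code in decision.reasons)


def iter_truth_table_grid():
    """The documented discretized cross-product for oracle equivalence."""
    flag_names = list(FLAG_CODES)
    for bits in itertools.product([False, True], repeat=len(flag_names)):
        flags = dict(zip(flag_names, bits))
        for bmi in BMI_GRID:
            for egfr in EGFR_GRID:
                yield flags, bmi, egfr


def assert_engine_matches_oracle(flags, bmi, egfr, diabetes_type="type2",
                                 age=70.0, meds=()):
    rec = record_for(flags, bmi, egfr, diabetes_type=diabetes_type, age=age, meds=meds)
    got = recommend(rec)
    # pancreatic cancer code C25 also marks generic cancer; MTC text marks
    # nothing else the rules consult, so the oracle flags map one-to-one
    ref = reference_decision(
        diabetes_type=diabetes_type,
        age=age,
        on_sglt2i=any("gliflozin" in m for m in meds),
        on_glp1ra=any("glutide" in m for m in meds),
        bmi=bmi,
        egfr=egfr,
        **flags,
    )
    assert (got.sglt2i.status, got.sglt2i.reasons) == ref["sglt2i"], (flags, bmi, egfr)
    assert (got.glp1ra.status, got.glp1ra.reasons) == ref["glp1ra"], (flags, bmi, egfr)
    assert got.any_recommended == ref["any_recommended"]


def test_truth_table_equivalence_full_grid():
    """Engine decisions equal the brute-force oracle over the whole grid."""
    for flags, bmi, egfr in iter_truth_table_grid():
        assert_engine_matches_oracle(flags, bmi, egfr)


@pytest.mark.parametrize("diabetes_type", ["type1", "none"])
@pytest.mark.parametrize("age", [17.0, 70.0])
@pytest.mark.parametrize("meds", [(), ("empagliflozin",), ("liraglutide",)])
def test_truth_table_equivalence_exclusion_axes(diabetes_type, age, meds):
    for flags in ({}, {"hf": True}, {"pancreatitis": True}):
        for bmi in (24.0, 35.0, None):
            for egfr in (10.0, 60.0, None):
                assert_engine_matches_oracle(
                    dict(flags), bmi, egfr, diabetes_type=diabetes_type,
                    age=age, meds=meds,
                )
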