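"""Evaluation statistics for the pre/post prescribing audit.

The primary contrast is a 2×2 exposure-by-outcome table (exposure =
post-intervention period, outcome = physician recommendation in the
discharge letter).  The reporting path is the crude odds ratio

    OR = (a·d) / (b·c),        se(log OR) = sqrt(1/a + 1/b + 1/c + 1/d),

with a Wald confidence interval on the log scale and a two-sided Wald p —
identical to the univariate logistic MLE for a single binary covariate,
which is also provided (via statsmodels) as a cross-check.  Tables with a
zero cell receive the Haldane–Anscombe +0.5 correction, flagged in the
estimate's ``method``.

Group comparisons follow the study's declared rules: Kolmogorov–Smirnov
normality screening at α = 0.05 choosing between Welch's t-test and the
Wilcoxon rank-sum test for continuous variables; chi-square (Fisher's exact
when any expected cell is below 5) for categorical ones.  Subgroup reports
give per-stratum pre/post rates and odds ratios in a forest-plot-ready
layout.
"""

from __future__ import annotations

import logging
import math
from typing import Callable, Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats as sps

from .comorbidity import CodeMap, classify_discharge, default_code_map, map_codes
from .emr_model import Cohort, PatientRecord
from .engine import Recommendation, diabetes_medication_count

__all__ = [
    "TwoByTwoTable",
    "EffectEstimate",
    "StratumResult",
    "SubgroupReport",
    "build_2x2",
    "crude_odds_ratio",
    "logistic_univariate",
    "fisher_exact",
    "chi_square",
    "compare_continuous",
    "cohort_frame",
    "subgroup_analysis",
    "baseline_table",
    "DEFAULT_STRATIFIERS",
]

logger = logging.getLogger(__name__)


class TwoByTwoTable(BaseModel):
    """Exposure × outcome counts: a/b exposed with/without the outcome,
    c/d unexposed with/without."""

    a: int = Field(ge=0)
    b: int = Field(ge=0)
    c: int = Field(ge=0)
    d: int = Field(ge=0)

    @model_validator(mode="after")
    def _nonempty(self) -> "TwoByTwoTable":
        if self.n < 1:
            raise ValueError("table must contain at least one observation")
        return self

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    def has_zero_margin(self) -> bool:
        return (
            self.a + self.b == 0
            or self.c + self.d == 0
            or self.a + self.c == 0
            or self.b + self.d == 0
        )


class EffectEstimate(BaseModel):
    """Odds ratio with Wald interval and two-sided p."""

    odds_ratio: float
    log_or: float
    se_log_or: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95
    p_value: float
    method: Literal["crude_wald", "logistic_mle", "haldane_corrected"]
    #: set when a zero margin leaves the OR unidentified even after the
    #: Haldane correction; the interval is then (0, inf)
    degenerate: bool = False


def build_2x2(
    records: Iterable,
    outcome: Callable[[object], Optional[bool]],
    exposure: Callable[[object], Optional[bool]],
) -> TwoByTwoTable:
    """Tally an exposure × outcome table from records and two predicates.

    Predicates may return ``None`` (missing); such records are dropped and
    counted in a log line.  Raises on an empty (or fully missing) input.
    """
    a = b = c = d = 0
    dropped = 0
    total = 0
    for rec in records:
        total += 1
        o, e = outcome(rec), exposure(rec)
        if o is None or e is None:
            dropped += 1
            continue
        if e:
            a, b = (a + 1, b) if o else (a, b + 1)
        else:
            c, d = (c + 1, d) if o else (c, d + 1)
    if dropped:
        logger.info("build_2x2: dropped %d/%d records with missing values", dropped, total)
    if a + b + c + d == 0:
        raise ValueError("no complete records to tabulate")
    return TwoByTwoTable(a=a, b=b, c=c, d=d)


def _z(ci_level: float) -> float:
    return float(sps.norm.ppf(0.5 + ci_level / 2.0))


def crude_odds_ratio(table: TwoByTwoTable, ci_level: float = 0.95) -> EffectEstimate:
    """Cross-product odds ratio with Wald CI and two-sided Wald p.

    A zero cell triggers the Haldane–Anscombe +0.5 correction on all four
    cells (``method="haldane_corrected"``).  A zero margin leaves the OR
    unidentified: the estimate is flagged ``degenerate`` with interval
    (0, inf) and p = 1 rather than raising.
    """
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")
    corrected = table.has_zero_cell()
    cells = [float(x) + (0.5 if corrected else 0.0) for x in (table.a, table.b, table.c, table.d)]
    a, b, c, d = cells
    log_or = math.log(a * d) - math.log(b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    method = "haldane_corrected" if corrected else "crude_wald"
    if table.has_zero_margin():
        return EffectEstimate(
            odds_ratio=math.exp(log_or),
            log_or=log_or,
            se_log_or=se,
            ci_low=0.0,
            ci_high=math.inf,
            ci_level=ci_level,
            p_value=1.0,
            method=method,
            degenerate=True,
        )
    z = _z(ci_level)
    wald = log_or / se
    return EffectEstimate(
        odds_ratio=math.exp(log_or),
        log_or=log_or,
        se_log_or=se,
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        ci_level=ci_level,
        p_value=float(2.0 * sps.norm.sf(abs(wald))),
        method=method,
    )


def logistic_univariate(
    outcome: Sequence, exposure: Sequence, ci_level: float = 0.95
) -> EffectEstimate:
    """Univariate logistic regression OR (intercept + binary exposure).

    Fit by iteratively reweighted least squares (statsmodels GLM, binomial
    family); exp(slope) is reported with a Wald interval.  Complete
    separation — any zero cell in the implied 2×2 table — cannot be fit by
    MLE and falls back to the Haldane-corrected crude estimate, flagged via
    ``method``.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("outcome and exposure must be equal-length vectors")
    if not (set(np.unique(y)) <= {0.0, 1.0} and set(np.unique(x)) <= {0.0, 1.0}):
        raise ValueError("outcome and exposure must be binary 0/1 vectors")
    if len(set(np.unique(y))) < 2 or len(set(np.unique(x))) < 2:
        raise ValueError("both levels of outcome and exposure must be present")

    table = TwoByTwoTable(
        a=int(np.sum((x == 1) & (y == 1))),
        b=int(np.sum((x == 1) & (y == 0))),
        c=int(np.sum((x == 0) & (y == 1))),
        d=int(np.sum((x == 0) & (y == 0))),
    )
    if table.has_zero_cell():
        logger.warning("logistic_univariate: separation detected, using corrected crude OR")
        return crude_odds_ratio(table, ci_level)

    design = sm.add_constant(x)
    fit = sm.GLM(y, design, family=sm.families.Binomial()).fit()
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    z = _z(ci_level)
    return EffectEstimate(
        odds_ratio=math.exp(beta),
        log_or=beta,
        se_log_or=se,
        ci_low=math.exp(beta - z * se),
        ci_high=math.exp(beta + z * se),
        ci_level=ci_level,
        p_value=float(2.0 * sps.norm.sf(abs(beta / se))),
        method="logistic_mle",
    )


def fisher_exact(table: TwoByTwoTable) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of all
    same-margin tables no more probable than the observed one."""
    _, p = sps.fisher_exact(table.as_array(), alternative="two-sided")
    return float(p)


def chi_square(table: TwoByTwoTable, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square statistic and two-sided p (1 df).

    Uses the closed form n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)); the Yates
    continuity correction is optional and off by default.  A zero margin is
    an error — use :func:`fisher_exact` for such tables.
    """
    if table.has_zero_margin():
        raise ValueError("zero margin: chi-square undefined, use fisher_exact")
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    n = a + b + c + d
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    stat = n * diff**2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return float(stat), float(sps.chi2.sf(stat, df=1))


def compare_continuous(
    x_pre: Sequence[float], y_post: Sequence[float], alpha: float = 0.05
) -> tuple[str, float]:
    """Compare a continuous variable between study groups.

    Each sample is screened for normality with a Kolmogorov–Smirnov test
    against a normal law with the sample's own mean and SD; if both pass at
    ``alpha`` the comparison is Welch's (unequal-variance) t-test, otherwise
    the Wilcoxon rank-sum test.  Returns ``(test_name, p)`` where test_name
    is ``"t_test"`` or ``"wilcoxon"``.
    """
    x = np.asarray(x_pre, dtype=float)
    y = np.asarray(y_post, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each group needs at least 3 observations")

    def _normal(sample: np.ndarray) -> bool:
        sd = sample.std(ddof=1)
        if sd == 0:
            return False
        return sps.kstest(sample, "norm", args=(sample.mean(), sd)).pvalue > alpha

    if _normal(x) and _normal(y):
        stat = sps.ttest_ind(x, y, equal_var=False)
        return "t_test", float(stat.pvalue)
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return "wilcoxon", float(res.pvalue)


# --- cohort-level reports ---------------------------------------------------

#: Comorbidity columns surfaced in the analysis frame and reports (the
#: study's Table 1 / forest-plot row set).
_COMORBIDITY_COLUMNS = [
    "ascvd",
    "heart_failure",
    "t2dm_complication",
    "cancer",
    "obesity",
    "ckd_moderate_severe",
    "liver_disease",
    "hypertension",
    "dyslipidemia",
]


def cohort_frame(
    cohort: Cohort,
    recommendations: Optional[Sequence[Recommendation]] = None,
    code_map: Optional[CodeMap] = None,
) -> pd.DataFrame:
    """Flatten a cohort into one analysis row per record.

    Columns: demographics, length of stay, the Table-1 comorbidity
    composites, diabetes-medication count, prednisone, discharge category,
    period, and the physician-recommendation outcome.  If engine outputs are
    supplied (aligned with the records) the per-class statuses are included.
    """
    cmap = code_map if code_map is not None else default_code_map()
    rows = []
    for i, rec in enumerate(cohort):
        prof = map_codes(rec.icd_codes, rec.problem_text, rec.bmi, cmap)
        row = {
            "patient_id": rec.patient_id,
            "period": rec.period,
            "age": rec.age,
            "sex": rec.sex,
            "los_days": rec.los_days,
            "bmi": rec.bmi,
            "egfr": rec.egfr,
            "hba1c": rec.hba1c,
            "ascvd": prof.ascvd,
            "heart_failure": prof.heart_failure,
            "t2dm_complication": prof.t2dm_complication,
            "cancer": prof.cancer_any,
            "obesity": prof.obesity,
            "ckd_moderate_severe": prof.ckd_moderate_severe,
            "liver_disease": prof.liver_disease_any,
            "hypertension": prof.hypertension,
            "dyslipidemia": prof.dyslipidemia,
            "diabetes_med_count": diabetes_medication_count(rec.medications),
            "prednisone": rec.prednisone_regular,
            "discharge_category": classify_discharge(rec.discharge_diagnosis_text, cmap),
            "physician_recommended": rec.physician_recommended,
        }
        if recommendations is not None:
            row["sglt2i_status"] = recommendations[i].sglt2i.status
            row["glp1ra_status"] = recommendations[i].glp1ra.status
            row["any_recommended"] = recommendations[i].any_recommended
        rows.append(row)
    return pd.DataFrame(rows)


class StratumResult(BaseModel):
    label: str
    n_pre: int
    n_post: int
    pre_rate_pct: Optional[float] = None
    post_rate_pct: Optional[float] = None
    estimate: Optional[EffectEstimate] = None


class SubgroupReport(BaseModel):
    """Per-stratifier pre/post rates and odds ratios (forest-table row set)."""

    stratifier: str
    strata: list[StratumResult]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.strata:
            est = s.estimate
            rows.append(
                {
                    "stratifier": self.stratifier,
                    "stratum": s.label,
                    "n_pre": s.n_pre,
                    "n_post": s.n_post,
                    "pre_rate_pct": s.pre_rate_pct,
                    "post_rate_pct": s.post_rate_pct,
                    "odds_ratio": est.odds_ratio if est else None,
                    "ci_low": est.ci_low if est else None,
                    "ci_high": est.ci_high if est else None,
                    "p_value": est.p_value if est else None,
                    "method": est.method if est else None,
                }
            )
        return pd.DataFrame(rows)


def _age_group(s: pd.Series) -> pd.Series:
    # a 75-year-old falls in the older stratum
    return pd.Series(np.where(s >= 75, ">=75", "<75"), index=s.index)


DEFAULT_STRATIFIERS: dict[str, Callable[[pd.DataFrame], pd.Series]] = {
    "age": lambda df: _age_group(df["age"]),
    "sex": lambda df: df["sex"],
    **{
        flag: (lambda df, f=flag: df[f].map({True: "yes", False: "no"}))
        for flag in _COMORBIDITY_COLUMNS
    },
    "diabetes_medications": lambda df: np.where(
        df["diabetes_med_count"] >= 1, ">=1", "0"
    ),
    "prednisone": lambda df: df["prednisone"].map({True: "yes", False: "no"}),
    "discharge_category": lambda df: df["discharge_category"],
}


def subgroup_analysis(
    df: pd.DataFrame,
    stratifiers: Optional[dict[str, Callable[[pd.DataFrame], pd.Series]]] = None,
    ci_level: float = 0.95,
) -> list[SubgroupReport]:
    """Stratified pre/post recommendation rates with crude odds ratios.

    ``df`` is an analysis frame from :func:`cohort_frame` with ``period`` and
    ``physician_recommended`` populated.  Strata with a zero cell get the
    Haldane-corrected estimate; strata empty in either period are reported
    with a missing estimate rather than raising.
    """
    strat = stratifiers if stratifiers is not None else DEFAULT_STRATIFIERS
    reports = []
    for name, fn in strat.items():
        labels = pd.Series(fn(df), index=df.index).astype(str)
        strata = []
        for label in sorted(labels.unique()):
            sub = df[labels == label]
            pre = sub[sub["period"] == "pre"]
            post = sub[sub["period"] == "post"]
            res = StratumResult(label=label, n_pre=len(pre), n_post=len(post))
            if len(pre):
                res.pre_rate_pct = 100.0 * pre["physician_recommended"].mean()
            if len(post):
                res.post_rate_pct = 100.0 * post["physician_recommended"].mean()
            if len(pre) and len(post):
                table = TwoByTwoTable(
                    a=int(post["physician_recommended"].sum()),
                    b=int((~post["physician_recommended"].astype(bool)).sum()),
                    c=int(pre["physician_recommended"].sum()),
                    d=int((~pre["physician_recommended"].astype(bool)).sum()),
                )
                res.estimate = crude_odds_ratio(table, ci_level)
            strata.append(res)
        reports.append(SubgroupReport(stratifier=name, strata=strata))
    return reports


def _categorical_test(table: TwoByTwoTable, fisher_threshold: float = 5.0) -> tuple[str, float]:
    """Chi-square, or Fisher's exact when any expected cell is small."""
    arr = table.as_array()
    rows = arr.sum(axis=1, keepdims=True)
    cols = arr.sum(axis=0, keepdims=True)
    n = arr.sum()
    if n == 0 or table.has_zero_margin():
        return "fisher", fisher_exact(table)
    expected = rows @ cols / n
    if (expected < fisher_threshold).any():
        return "fisher", fisher_exact(table)
    stat, p = chi_square(table)
    return "chi_square", p


def _categorical_row(
    pre_mask: pd.Series, post_mask: pd.Series, fisher_threshold: float = 5.0
) -> tuple[str, Optional[float]]:
    a = int(post_mask.sum())
    b = int((~post_mask).sum())
    c = int(pre_mask.sum())
    d = int((~pre_mask).sum())
    if a + b == 0 or c + d == 0:
        return "none", None
    return _categorical_test(TwoByTwoTable(a=a, b=b, c=c, d=d), fisher_threshold)


def baseline_table(df: pd.DataFrame, fisher_threshold: float = 5.0) -> pd.DataFrame:
    """Baseline-characteristics comparison of the pre and post groups.

    Row set mirrors the study's Table 1: age (mean ± SD, normality-routed
    test), length of stay (median (IQR), Wilcoxon), sex, the comorbidity
    composites, diabetes-medication use, prednisone, and discharge-diagnosis
    categories (N,% with chi-square or Fisher).  Rows with an empty group are
    rendered with a missing p-value.
    """
    pre = df[df["period"] == "pre"]
    post = df[df["period"] == "post"]
    rows: list[dict] = []

    def _fmt_mean_sd(s: pd.Series) -> str:
        return f"{s.mean():.1f} ± {s.std(ddof=1):.1f}" if len(s) else ""

    def _fmt_median_iqr(s: pd.Series) -> str:
        if not len(s):
            return ""
        q1, med, q3 = s.quantile([0.25, 0.5, 0.75])
        return f"{med:g} ({q1:g}–{q3:g})"

    def _fmt_pct(mask: pd.Series) -> str:
        return f"{100.0 * mask.mean():.1f}%" if len(mask) else ""

    # age: mean +- SD with the declared normality-routed test
    if len(pre) >= 3 and len(post) >= 3:
        test, p = compare_continuous(pre["age"], post["age"])
    else:
        test, p = "none", None
    rows.append(
        {
            "characteristic": "age_years",
            "statistic": "mean_sd",
            "pre": _fmt_mean_sd(pre["age"]),
            "post": _fmt_mean_sd(post["age"]),
            "test": test,
            "p_value": p,
        }
    )

    # length of stay: median (IQR), Wilcoxon as declared
    if len(pre) >= 3 and len(post) >= 3:
        p_los = float(
            sps.mannwhitneyu(pre["los_days"], post["los_days"], alternative="two-sided").pvalue
        )
        test_los = "wilcoxon"
    else:
        p_los, test_los = None, "none"
    rows.append(
        {
            "characteristic": "los_days",
            "statistic": "median_iqr",
            "pre": _fmt_median_iqr(pre["los_days"]),
            "post": _fmt_median_iqr(post["los_days"]),
            "test": test_los,
            "p_value": p_los,
        }
    )

    def _add_categorical(name: str, pre_mask: pd.Series, post_mask: pd.Series) -> None:
        test, p = _categorical_row(pre_mask, post_mask, fisher_threshold)
        rows.append(
            {
                "characteristic": name,
                "statistic": "n_pct",
                "pre": _fmt_pct(pre_mask),
                "post": _fmt_pct(post_mask),
                "test": test,
                "p_value": p,
            }
        )

    _add_categorical("sex_male", pre["sex"] == "male", post["sex"] == "male")
    for flag in _COMORBIDITY_COLUMNS:
        _add_categorical(flag, pre[flag].astype(bool), post[flag].astype(bool))
    _add_categorical(
        "diabetes_medications_ge1",
        pre["diabetes_med_count"] >= 1,
        post["diabetes_med_count"] >= 1,
    )
    _add_categorical("prednisone", pre["prednisone"].astype(bool), post["prednisone"].astype(bool))
    for cat in ("t2dm_complication", "heart_failure", "ihd", "ischemic_stroke", "ckd", "other"):
        _add_categorical(
            f"discharge_{cat}",
            pre["discharge_category"] == cat,
            post["discharge_category"] == cat,
        )
    return pd.DataFrame(rows)
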