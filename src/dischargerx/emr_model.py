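"""Patient-level EMR containers and tabular interchange I/O.

A :class:`PatientRecord` is one hospitalization extracted from an electronic
medical record: demographics, admission/discharge dates, labs (HbA1c, BMI,
eGFR), ICD-10 diagnosis codes, free-text problem-list strings, current
medications, and the discharge diagnosis.  A :class:`Cohort` is an ordered
collection of records plus provenance metadata.

Cohorts round-trip losslessly through two plain-text formats:

* CSV — UTF-8, comma-delimited, ISO-8601 dates, semicolon-separated
  multi-valued cells, empty cell for a missing value (never a sentinel
  number);
* JSONL — one JSON object per line, native lists, ``null`` for missing.

Records are assigned to the pre- or post-intervention period by their
*discharge* date (the recommendation event occurs at discharge) against
inclusive window bounds, and deduplicated to the first hospitalization per
patient within each period.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
import re
from pathlib import Path
from typing import Iterator, Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "PatientRecord",
    "PeriodWindows",
    "Cohort",
    "CohortReadError",
    "DEFAULT_PERIODS",
    "CSV_COLUMNS",
    "normalize_icd",
    "assign_period",
    "assign_periods",
    "dedupe_first_hospitalization",
    "read_cohort",
    "write_cohort",
]

Sex = Literal["male", "female"]
DiabetesType = Literal["type1", "type2", "none"]
Period = Literal["pre", "post"]

#: ICD-10 lexical shape after normalization: letter, two digits, short suffix.
ICD10_PATTERN = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]{0,5}$")


def normalize_icd(code: str) -> str:
    """Uppercase an ICD-10 code and strip the dot and surrounding whitespace.

    Normalization is purely lexical; whether the result matches the ICD-10
    pattern is checked by the consumer (unmatchable codes are ignored by the
    comorbidity mapper, not rejected here).
    """
    return code.strip().upper().replace(".", "")


class PatientRecord(BaseModel):
    """One hospitalization's EMR extract."""

    patient_id: str
    admission_date: dt.date
    discharge_date: dt.date
    ward_id: str = ""
    age: float = Field(ge=0)
    sex: Sex
    diabetes_type: DiabetesType
    hba1c: Optional[float] = Field(default=None, ge=0)
    bmi: Optional[float] = Field(default=None, ge=0)
    egfr: Optional[float] = Field(default=None, ge=0)
    serum_creatinine: Optional[float] = Field(default=None, ge=0)
    icd_codes: list[str] = Field(default_factory=list)
    problem_text: list[str] = Field(default_factory=list)
    medications: list[str] = Field(default_factory=list)
    prednisone_regular: bool = False
    discharge_diagnosis_text: str = ""
    period: Optional[Period] = None
    #: observed study outcome: did the discharging physician recommend the
    #: drug class in the discharge letter (distinct from the algorithm output)
    physician_recommended: Optional[bool] = None

    @field_validator("icd_codes", mode="after")
    @classmethod
    def _normalize_codes(cls, codes: list[str]) -> list[str]:
        return [normalize_icd(c) for c in codes if c.strip()]

    @model_validator(mode="after")
    def _check_dates(self) -> "PatientRecord":
        if self.discharge_date < self.admission_date:
            raise ValueError(
                f"discharge_date {self.discharge_date} precedes "
                f"admission_date {self.admission_date}"
            )
        return self

    @property
    def los_days(self) -> int:
        """Length of stay in whole days (discharge minus admission)."""
        return (self.discharge_date - self.admission_date).days


class PeriodWindows(BaseModel):
    """Inclusive calendar windows defining the pre and post periods."""

    pre_start: dt.date
    pre_end: dt.date
    post_start: dt.date
    post_end: dt.date

    @model_validator(mode="after")
    def _check_order(self) -> "PeriodWindows":
        if self.pre_end < self.pre_start or self.post_end < self.post_start:
            raise ValueError("period windows must be non-empty")
        if not self.pre_end < self.post_start:
            raise ValueError("pre window must end before post window starts")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PeriodWindows":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh))


#: Study windows: calendar year 2021 vs 1 April – 6 October 2023.
DEFAULT_PERIODS = PeriodWindows(
    pre_start=dt.date(2021, 1, 1),
    pre_end=dt.date(2021, 12, 31),
    post_start=dt.date(2023, 4, 1),
    post_end=dt.date(2023, 10, 6),
)


class Cohort(BaseModel):
    """Ordered collection of patient records with provenance metadata."""

    records: list[PatientRecord] = Field(default_factory=list)
    metadata: dict = Field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:  # type: ignore[override]
        return iter(self.records)

    def __getitem__(self, i: int) -> PatientRecord:
        return self.records[i]


class CohortReadError(ValueError):
    """Raised in strict mode when any record fails to parse.

    ``errors`` holds one ``{"row": int, "error": str}`` entry per bad record
    (row numbers are 1-based over data rows/lines).
    """

    def __init__(self, errors: list[dict]):
        self.errors = errors
        lines = "; ".join(f"row {e['row']}: {e['error']}" for e in errors[:5])
        more = "" if len(errors) <= 5 else f" (+{len(errors) - 5} more)"
        super().__init__(f"{len(errors)} record(s) failed to parse: {lines}{more}")


def assign_period(
    record: PatientRecord, windows: PeriodWindows = DEFAULT_PERIODS
) -> str:
    """Classify a record as ``pre``, ``post`` or ``out_of_window``.

    Keyed on the discharge date against inclusive bounds.
    """
    d = record.discharge_date
    if windows.pre_start <= d <= windows.pre_end:
        return "pre"
    if windows.post_start <= d <= windows.post_end:
        return "post"
    return "out_of_window"


def assign_periods(
    cohort: Cohort, windows: PeriodWindows = DEFAULT_PERIODS
) -> Cohort:
    """Return a cohort with each record's ``period`` field set.

    Records falling outside both windows get ``period=None``.
    """
    out = []
    for rec in cohort:
        label = assign_period(rec, windows)
        out.append(
            rec.model_copy(update={"period": label if label != "out_of_window" else None})
        )
    return Cohort(records=out, metadata=dict(cohort.metadata))


def dedupe_first_hospitalization(cohort: Cohort) -> Cohort:
    """Keep only the first hospitalization per (patient, period).

    Within each (patient_id, period) group, the record with the earliest
    admission date survives; ties keep the first in input order.  Dedup is
    per-period: a patient may contribute one record to the pre period and one
    to the post period.  Survivor ordering follows the input.  Idempotent.
    """
    best: dict[tuple[str, Optional[str]], int] = {}
    for i, rec in enumerate(cohort):
        key = (rec.patient_id, rec.period)
        j = best.get(key)
        if j is None or rec.admission_date < cohort[j].admission_date:
            best[key] = i
    keep = sorted(best.values())
    return Cohort(
        records=[cohort[i] for i in keep], metadata=dict(cohort.metadata)
    )


# --- tabular I/O -----------------------------------------------------------

CSV_COLUMNS = [
    "patient_id",
    "admission_date",
    "discharge_date",
    "ward_id",
    "age",
    "sex",
    "diabetes_type",
    "hba1c",
    "bmi",
    "egfr",
    "serum_creatinine",
    "icd_codes",
    "problem_text",
    "medications",
    "prednisone_regular",
    "discharge_diagnosis_text",
    "period",
    "physician_recommended",
]

_LIST_FIELDS = {"icd_codes", "problem_text", "medications"}
_FLOAT_FIELDS = {"age", "hba1c", "bmi", "egfr", "serum_creatinine"}
_BOOL_FIELDS = {"prednisone_regular", "physician_recommended"}
_MANDATORY = {"patient_id", "admission_date", "discharge_date", "age", "sex", "diabetes_type"}


def _infer_format(path: str | Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("csv", "jsonl"):
            raise ValueError(f"unknown format {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower()
    return "jsonl" if suffix in (".jsonl", ".ndjson", ".json") else "csv"


def _cell_to_value(field: str, cell: str):
    cell = cell.strip()
    if cell == "":
        return [] if field in _LIST_FIELDS else None
    if field in _LIST_FIELDS:
        return [p for p in (s.strip() for s in cell.split(";")) if p]
    if field in _FLOAT_FIELDS:
        return float(cell)
    if field in _BOOL_FIELDS:
        low = cell.lower()
        if low in ("true", "1", "yes"):
            return True
        if low in ("false", "0", "no"):
            return False
        raise ValueError(f"unparseable boolean {cell!r} for {field}")
    return cell


def _value_to_cell(field: str, value) -> str:
    if value is None:
        return ""
    if field in _LIST_FIELDS:
        return ";".join(value)
    if field in _BOOL_FIELDS:
        return "true" if value else "false"
    if isinstance(value, dt.date):
        return value.isoformat()
    if isinstance(value, float) and value == int(value):
        # keep integral floats compact but unambiguous on re-read
        return repr(value)
    return str(value)


def read_cohort(
    path: str | Path, format: Optional[str] = None, strict: bool = True
) -> Cohort:
    """Read a cohort from a CSV or JSONL file.

    Missing optional fields become missing values (``None``), never zero.
    Malformed records (bad date, non-numeric lab, unknown sex token, ...)
    produce a per-record error report with the row number.  In strict mode
    any error aborts with :class:`CohortReadError`; in permissive mode bad
    records are dropped and the report is stored under
    ``cohort.metadata["read_errors"]``.
    """
    fmt = _infer_format(path, format)
    rows: list[tuple[int, dict]] = []
    errors: list[dict] = []

    if fmt == "csv":
        with open(path, "r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            header = set(reader.fieldnames or [])
            missing = _MANDATORY - header
            if missing:
                raise ValueError(f"missing mandatory columns: {sorted(missing)}")
            for i, row in enumerate(reader, start=1):
                try:
                    data = {
                        k: _cell_to_value(k, v)
                        for k, v in row.items()
                        if k in set(CSV_COLUMNS) and v is not None
                    }
                    # missing optional fields stay at their model default
                    rows.append((i, {k: v for k, v in data.items() if v is not None}))
                except (ValueError, TypeError) as exc:
                    errors.append({"row": i, "error": str(exc)})
    else:
        with open(path, "r", encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rows.append((i, json.loads(line)))
                except json.JSONDecodeError as exc:
                    errors.append({"row": i, "error": f"invalid JSON: {exc}"})

    records: list[PatientRecord] = []
    for i, data in rows:
        try:
            records.append(PatientRecord.model_validate(data))
        except Exception as exc:  # pydantic ValidationError or ValueError
            errors.append({"row": i, "error": _short_error(exc)})

    if errors and strict:
        raise CohortReadError(sorted(errors, key=lambda e: e["row"]))
    metadata: dict = {"source": str(path), "format": fmt}
    if errors:
        metadata["read_errors"] = sorted(errors, key=lambda e: e["row"])
    return Cohort(records=records, metadata=metadata)


def _short_error(exc: Exception) -> str:
    text = str(exc)
    return text if len(text) <= 300 else text[:297] + "..."


def write_cohort(
    cohort: Cohort, path: str | Path, format: Optional[str] = None
) -> None:
    """Write a cohort to CSV or JSONL; output is re-readable without loss."""
    fmt = _infer_format(path, format)
    if fmt == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(CSV_COLUMNS)
            for rec in cohort:
                dumped = rec.model_dump()
                writer.writerow(
                    [_value_to_cell(col, dumped[col]) for col in CSV_COLUMNS]
                )
    else:
        with open(path, "w", encoding="utf-8") as fh:
            for rec in cohort:
                fh.write(rec.model_dump_json() + "\n")
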