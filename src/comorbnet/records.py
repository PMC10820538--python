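"""Discharge-record data model, ICD-10 code handling, cohort filters and CSV I/O.

A record is one hospitalization: demographics, admission/outcome fields, a
principal ICD-10 diagnosis and a list of secondary (comorbidity) diagnoses.
Diagnoses are analyzed at the 3-character category level (e.g. ``E11`` for
``E11.9``); the cohort of interest is adults (age >= 19) admitted with a
principal diagnosis in the endocrine chapter E00-E90.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

__all__ = [
    "Icd10Code",
    "DischargeRecord",
    "AGE_GROUPS",
    "parse_icd10",
    "is_endocrine_principal",
    "assign_age_group",
    "filter_cohort",
    "read_records",
    "write_records",
]

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}[A-Z0-9]*$")

#: Life-cycle age strata (inclusive bounds as labeled); they partition ages >= 19.
AGE_GROUPS = ("19–44", "45–64", "65–74", "≥75")

SEXES = ("male", "female")
INSURANCE_TYPES = ("national_health", "medicaid1", "medicaid2", "other")
ADMISSION_ROUTES = ("emergency", "outpatient", "other")
TREATMENT_OUTCOMES = ("improved", "not_improved", "death", "other")
BED_SIZES = ("100–299", "300–499", "500–999", "≥1000")

# Common ASCII spellings accepted on input; canonical labels used on output.
_BED_SIZE_ALIASES = {
    "100-299": BED_SIZES[0],
    "300-499": BED_SIZES[1],
    "500-999": BED_SIZES[2],
    ">=1000": BED_SIZES[3],
    "1000+": BED_SIZES[3],
}


@dataclass(frozen=True)
class Icd10Code:
    """An ICD-10 diagnosis code with its 3-character category.

    ``raw`` preserves the code as coded (dotted or undotted, any case);
    ``category`` is the normalized 3-character group used throughout the
    analysis.
    """

    raw: str
    category: str

    def __post_init__(self) -> None:
        if not re.match(r"^[A-Z][0-9][0-9]$", self.category):
            raise ValueError(f"invalid ICD-10 category: {self.category!r}")


def parse_icd10(text: str) -> Icd10Code:
    """Parse an ICD-10 code, normalizing to upper case without the dot.

    Accepts dotted (``E11.9``) and undotted (``E119``) forms; national
    extensions beyond the 3-character category are kept in ``raw`` but the
    category is always the first three characters.

    Raises
    ------
    ValueError
        If the text does not look like an ICD-10 code (letter + two digits).
    """
    raw = text.strip()
    if not raw:
        raise ValueError("empty ICD-10 code")
    compact = raw.upper().replace(".", "")
    if len(compact) < 3 or not _CODE_RE.match(compact):
        raise ValueError(f"malformed ICD-10 code: {text!r}")
    return Icd10Code(raw=raw, category=compact[:3])


def is_endocrine_principal(code: Icd10Code) -> bool:
    """True iff the category lies in the endocrine chapter range E00-E90 (inclusive)."""
    return "E00" <= code.category <= "E90"


def assign_age_group(age: int) -> str:
    """Map an adult age to its life-cycle stratum: 19-44, 45-64, 65-74, >=75."""
    if age < 19:
        raise ValueError(f"age {age} below adult cohort (>= 19); filter the cohort first")
    if age <= 44:
        return AGE_GROUPS[0]
    if age <= 64:
        return AGE_GROUPS[1]
    if age <= 74:
        return AGE_GROUPS[2]
    return AGE_GROUPS[3]


@dataclass(frozen=True)
class DischargeRecord:
    """One hospitalization with demographics and coded diagnoses.

    ``secondary_dx`` is deduplicated at the category level during
    normalization (transactions are sets of categories); ``death`` is kept
    consistent with ``treatment_outcome``.
    """

    patient_id: str
    sex: str
    age: int
    insurance_type: str
    admission_route: str
    treatment_outcome: str
    length_of_stay: int
    death: bool
    surgery: bool
    bed_size: str
    principal_dx: Icd10Code
    secondary_dx: tuple[Icd10Code, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"negative age: {self.age}")
        if self.length_of_stay < 0:
            raise ValueError(f"negative length of stay: {self.length_of_stay}")
        if self.death != (self.treatment_outcome == "death"):
            raise ValueError("death flag inconsistent with treatment outcome")

    def normalized(self) -> "DischargeRecord":
        """Deduplicate secondary diagnoses at the category level (first wins)."""
        seen: set[str] = set()
        kept = []
        for code in self.secondary_dx:
            if code.category not in seen:
                seen.add(code.category)
                kept.append(code)
        return replace(self, secondary_dx=tuple(kept))

    @property
    def age_group(self) -> str:
        return assign_age_group(self.age)

    @property
    def secondary_categories(self) -> frozenset[str]:
        return frozenset(c.category for c in self.secondary_dx)


def filter_cohort(records: list[DischargeRecord]) -> list[DischargeRecord]:
    """Retain adult records (age >= 19) with an endocrine principal diagnosis.

    Order-preserving and idempotent; the number of removals is logged.
    """
    kept = [
        r
        for r in records
        if r.age >= 19 and is_endocrine_principal(r.principal_dx)
    ]
    removed = len(records) - len(kept)
    if removed:
        logger.info("cohort filter removed %d of %d records", removed, len(records))
    return kept


_COLUMNS = [
    "patient_id",
    "sex",
    "age",
    "insurance_type",
    "admission_route",
    "treatment_outcome",
    "length_of_stay",
    "death",
    "surgery",
    "bed_size",
    "principal_dx",
    "secondary_dx",
]


def _parse_level(value: str, levels: tuple[str, ...], *, row: int, col: str) -> str:
    v = value.strip()
    if v in levels:
        return v
    if "other" in levels:
        # unknown/missing categorical values map to the explicit "other" level
        return "other"
    raise ValueError(f"row {row}: unrecognized {col} value {value!r}")


def _parse_bed_size(value: str, *, row: int) -> str:
    v = value.strip()
    if v in BED_SIZES:
        return v
    if v in _BED_SIZE_ALIASES:
        return _BED_SIZE_ALIASES[v]
    raise ValueError(f"row {row}: unrecognized bed_size value {value!r}")


def _parse_bool(value: str, *, row: int, col: str) -> bool:
    v = value.strip().lower()
    if v in ("true", "1", "yes", "y"):
        return True
    if v in ("false", "0", "no", "n", ""):
        return False
    raise ValueError(f"row {row}: unparseable boolean in {col}: {value!r}")


def read_records(path) -> list[DischargeRecord]:
    """Read discharge records from CSV (UTF-8, header row).

    ``secondary_dx`` is a semicolon-separated list of ICD-10 codes (empty
    allowed). Errors name the offending row number. Records are normalized
    on read (category-level deduplication of secondary codes).
    """
    records: list[DischargeRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _COLUMNS if c not in header]
        if missing:
            raise ValueError(f"missing required column(s): {', '.join(missing)}")
        for i, row in enumerate(reader, start=2):  # 1 is the header line
            try:
                age = int(row["age"])
            except ValueError:
                raise ValueError(f"row {i}: unparseable age {row['age']!r}") from None
            try:
                los = int(row["length_of_stay"])
            except ValueError:
                raise ValueError(
                    f"row {i}: unparseable length_of_stay {row['length_of_stay']!r}"
                ) from None
            try:
                principal = parse_icd10(row["principal_dx"])
                secondary = tuple(
                    parse_icd10(tok)
                    for tok in row["secondary_dx"].split(";")
                    if tok.strip()
                )
            except ValueError as e:
                raise ValueError(f"row {i}: {e}") from None
            outcome = _parse_level(
                row["treatment_outcome"], TREATMENT_OUTCOMES, row=i, col="treatment_outcome"
            )
            rec = DischargeRecord(
                patient_id=row["patient_id"],
                sex=_parse_level(row["sex"], SEXES, row=i, col="sex"),
                age=age,
                insurance_type=_parse_level(
                    row["insurance_type"], INSURANCE_TYPES, row=i, col="insurance_type"
                ),
                admission_route=_parse_level(
                    row["admission_route"], ADMISSION_ROUTES, row=i, col="admission_route"
                ),
                treatment_outcome=outcome,
                length_of_stay=los,
                death=outcome == "death",
                surgery=_parse_bool(row["surgery"], row=i, col="surgery"),
                bed_size=_parse_bed_size(row["bed_size"], row=i),
                principal_dx=principal,
                secondary_dx=secondary,
            )
            records.append(rec.normalized())
    return records


def write_records(records: list[DischargeRecord], path) -> None:
    """Write records to CSV in the documented dialect (round-trips with read_records)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    r.sex,
                    r.age,
                    r.insurance_type,
                    r.admission_route,
                    r.treatment_outcome,
                    r.length_of_stay,
                    str(r.death).lower(),
                    str(r.surgery).lower(),
                    r.bed_size,
                    r.principal_dx.raw,
                    ";".join(c.raw for c in r.secondary_dx),
                ]
            )
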