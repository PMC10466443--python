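"""Structured-data arm: ICD-10-CM Z-code classification and cohort selection.

Each social-risk domain is mapped to a grouping of Z-code stems (shipped in
``data/domain_codes.csv``); a patient is structured-positive for a domain when
any diagnosis code equals a stem or extends it with further digits, so the
grouping respects the ICD-10-CM hierarchy (Z59.4 covers Z59.41).

Cohort selection mirrors a primary-care diabetes phenotype: at least two
completed primary-care encounters on distinct dates inside the study window
plus at least one E10/E11 (type 1/2 diabetes) encounter diagnosis, adults
only when ages are available.
"""

from __future__ import annotations

import csv
import datetime as _dt
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

from .domains import DOMAINS

__all__ = [
    "DiagnosisRecord",
    "Encounter",
    "DomainCodeMap",
    "normalize_code",
    "load_default_code_map",
    "classify_patient_structured",
    "classify_patients_structured",
    "select_diabetes_cohort",
    "STUDY_WINDOW",
]

#: Default study window: two calendar years.
STUDY_WINDOW: tuple[_dt.date, _dt.date] = (_dt.date(2018, 1, 1), _dt.date(2019, 12, 31))

_CODE_RE = re.compile(r"^[A-Z][0-9][0-9A-Z][0-9A-Z]{0,4}$")


@dataclass(frozen=True)
class DiagnosisRecord:
    patient_id: str
    code: str
    date: _dt.date


@dataclass(frozen=True)
class Encounter:
    patient_id: str
    department_class: str  # "primary care" | "specialty" | "other"
    date: _dt.date
    completed: bool


def normalize_code(raw: str, default_letter: str | None = None) -> str:
    """Normalize an ICD-10-CM code to uppercase dotted form.

    Accepts codes with or without the dot ("z59.41", "Z5941" -> "Z59.41").
    A bare numeric grouping such as "59.4" (the form some summary tables
    print) is rejected unless ``default_letter`` supplies the chapter letter.
    """
    if not raw or not raw.strip():
        raise ValueError("empty ICD-10-CM code")
    stripped = raw.strip().upper()
    if "." in stripped:
        head, _, tail = stripped.partition(".")
        expected = 3 if head[:1].isalpha() else 2  # 2 when the chapter letter is omitted
        if len(head) != expected or "." in tail:
            raise ValueError(f"malformed ICD-10-CM code: {raw!r}")
    code = stripped.replace(".", "")
    if code[0].isdigit():
        if default_letter is None:
            raise ValueError(
                f"bare numeric code {raw!r}: supply a chapter letter to interpret it"
            )
        code = default_letter.upper() + code
    if not _CODE_RE.match(code):
        raise ValueError(f"malformed ICD-10-CM code: {raw!r}")
    return code if len(code) == 3 else f"{code[:3]}.{code[3:]}"


def _undot(code: str) -> str:
    return code.replace(".", "")


class DomainCodeMap:
    """Domain -> set of normalized Z-code stems, with hierarchical matching."""

    def __init__(self, stems: Mapping[str, Iterable[str]]) -> None:
        self._stems: dict[str, frozenset[str]] = {
            domain: frozenset(normalize_code(c) for c in codes)
            for domain, codes in stems.items()
        }

    @property
    def domains(self) -> tuple[str, ...]:
        return tuple(self._stems)

    def stems(self, domain: str) -> frozenset[str]:
        return self._stems[domain]

    def matches(self, domain: str, code: str) -> bool:
        """True when ``code`` equals a stem or is a descendant of one."""
        undotted = _undot(code)
        return any(undotted.startswith(_undot(stem)) for stem in self._stems[domain])

    def as_records(self) -> list[tuple[str, str]]:
        return [
            (domain, stem)
            for domain in self._stems
            for stem in sorted(self._stems[domain])
        ]


def load_default_code_map(widen_social: bool = False) -> DomainCodeMap:
    """The packaged seven-domain Z-code grouping.

    ``widen_social=True`` swaps the listed social-isolation subcodes
    (Z60.2/Z60.4/Z60.8) for the whole Z60 category, for sensitivity analyses
    of that grouping.
    """
    stems: dict[str, set[str]] = {domain: set() for domain in DOMAINS}
    path = resources.files("sdohscan.data").joinpath("domain_codes.csv")
    with path.open(encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            stems[row["domain"]].add(row["code_stem"])
    if widen_social:
        stems["social_connections"] = {"Z60"}
    return DomainCodeMap(stems)


def classify_patient_structured(
    records: Iterable[DiagnosisRecord], code_map: DomainCodeMap
) -> dict[str, bool]:
    """Per-domain flags from one patient's diagnosis records."""
    flags = {domain: False for domain in code_map.domains}
    for record in records:
        code = normalize_code(record.code)
        for domain in code_map.domains:
            if not flags[domain] and code_map.matches(domain, code):
                flags[domain] = True
    return flags


def classify_patients_structured(
    diagnoses: Iterable[DiagnosisRecord],
    code_map: DomainCodeMap,
    patients: Iterable[str] | None = None,
) -> dict[str, dict[str, bool]]:
    """Per-patient per-domain flags over a diagnosis stream; ``patients``
    optionally supplies the full cohort so code-free patients get all-false
    rows."""
    by_patient: dict[str, list[DiagnosisRecord]] = {}
    if patients is not None:
        for pid in patients:
            by_patient[pid] = []
    for record in diagnoses:
        by_patient.setdefault(record.patient_id, []).append(record)
    return {
        pid: classify_patient_structured(records, code_map)
        for pid, records in by_patient.items()
    }


def select_diabetes_cohort(
    encounters: Iterable[Encounter],
    diagnoses: Iterable[DiagnosisRecord],
    window: tuple[_dt.date, _dt.date] = STUDY_WINDOW,
    ages: Mapping[str, float] | None = None,
) -> set[str]:
    """Primary-care diabetes cohort.

    Included: >= 2 completed primary-care encounters on distinct dates inside
    the closed ``window`` and >= 1 diagnosis in E10/E11 (or a child code)
    dated inside the window.  When ``ages`` is given, patients under 18 are
    dropped; when absent, all patients are treated as adults.
    """
    start, end = window
    visit_dates: dict[str, set[_dt.date]] = {}
    for enc in encounters:
        if (
            enc.completed
            and enc.department_class == "primary care"
            and start <= enc.date <= end
        ):
            visit_dates.setdefault(enc.patient_id, set()).add(enc.date)
    diabetic: set[str] = set()
    for record in diagnoses:
        if start <= record.date <= end:
            code = _undot(normalize_code(record.code))
            if code.startswith("E10") or code.startswith("E11"):
                diabetic.add(record.patient_id)
    cohort = {pid for pid, dates in visit_dates.items() if len(dates) >= 2} & diabetic
    if ages is not None:
        cohort = {pid for pid in cohort if ages.get(pid, 18) >= 18}
    return cohort
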