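"""Readers and writers for the pipeline's plain-text interchange formats.

Notes travel as JSONL (one object per note: note_id, patient_id, note_type,
date as ISO-8601, text); diagnoses, encounters, review labels, matches and
synthetic ground truth travel as CSV.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .coding import DiagnosisRecord, Encounter
from .engine import ClinicalNote, MatchResult
from .review import ReviewLabel
from .synth import GroundTruth

__all__ = [
    "read_notes_jsonl",
    "write_notes_jsonl",
    "read_diagnoses_csv",
    "write_diagnoses_csv",
    "read_encounters_csv",
    "write_encounters_csv",
    "write_matches_csv",
    "read_labels_csv",
    "write_labels_csv",
    "write_truth_csv",
]


def _parse_date(value: str) -> _dt.date:
    return _dt.date.fromisoformat(str(value))


def read_notes_jsonl(path: str | Path) -> list[ClinicalNote]:
    notes = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            if not line.strip():
                continue
            obj = json.loads(line)
            notes.append(
                ClinicalNote(
                    note_id=str(obj["note_id"]),
                    patient_id=str(obj["patient_id"]),
                    note_type=obj["note_type"],
                    date=_parse_date(obj["date"]),
                    text=obj["text"],
                )
            )
    return notes


def write_notes_jsonl(notes: Iterable[ClinicalNote], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for note in notes:
            handle.write(
                json.dumps(
                    {
                        "note_id": note.note_id,
                        "patient_id": note.patient_id,
                        "note_type": note.note_type,
                        "date": note.date.isoformat(),
                        "text": note.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_diagnoses_csv(path: str | Path) -> list[DiagnosisRecord]:
    frame = pd.read_csv(path, dtype=str)
    return [
        DiagnosisRecord(
            patient_id=row.patient_id, code=row.code, date=_parse_date(row.date)
        )
        for row in frame.itertuples()
    ]


def write_diagnoses_csv(records: Iterable[DiagnosisRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"patient_id": r.patient_id, "code": r.code, "date": r.date.isoformat()}
            for r in records
        ]
    ).to_csv(path, index=False)


def read_encounters_csv(path: str | Path) -> list[Encounter]:
    frame = pd.read_csv(path, dtype=str)
    return [
        Encounter(
            patient_id=row.patient_id,
            department_class=row.department_class,
            date=_parse_date(row.date),
            completed=str(row.completed).lower() in ("true", "1", "yes"),
        )
        for row in frame.itertuples()
    ]


def write_encounters_csv(encounters: Iterable[Encounter], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "department_class": e.department_class,
                "date": e.date.isoformat(),
                "completed": e.completed,
            }
            for e in encounters
        ]
    ).to_csv(path, index=False)


def _format_evidence(result: MatchResult) -> str:
    return ";".join(
        f"{' '.join(span.matched_terms)}@{span.start}-{span.end}"
        for span in result.evidence
    )


def write_matches_csv(matches: Iterable[MatchResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "note_id": m.note_id,
                "patient_id": m.patient_id,
                "domain": m.domain,
                "positive": m.positive,
                "exclude_hit": m.exclude_hit,
                "evidence": _format_evidence(m),
            }
            for m in matches
        ]
    ).to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> list[ReviewLabel]:
    frame = pd.read_csv(path, dtype=str)
    return [
        ReviewLabel(
            unit_id=row.unit_id,
            domain=row.domain,
            reviewer_id=row.reviewer_id,
            label=row.label,
        )
        for row in frame.itertuples()
    ]


def write_labels_csv(labels: Iterable[ReviewLabel], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "unit_id": l.unit_id,
                "domain": l.domain,
                "reviewer_id": l.reviewer_id,
                "label": l.label,
            }
            for l in labels
        ]
    ).to_csv(path, index=False)


def write_truth_csv(truth: Sequence[GroundTruth], path: str | Path) -> None:
    """Ground truth as long CSV: one row per patient x domain, with planted
    snippet note ids (semicolon-joined per kind)."""
    rows = []
    for gt in truth:
        plants_by_domain: dict[tuple[str, str], list[str]] = {}
        for p in gt.plants:
            plants_by_domain.setdefault((p.domain, p.kind), []).append(p.note_id)
        for domain, is_case in gt.cases.items():
            rows.append(
                {
                    "patient_id": gt.patient_id,
                    "domain": domain,
                    "is_case": is_case,
                    "tp_notes": ";".join(
                        plants_by_domain.get((domain, "true_positive"), [])
                    ),
                    "confusable_notes": ";".join(
                        plants_by_domain.get((domain, "confusable"), [])
                    ),
                    "negation_notes": ";".join(
                        plants_by_domain.get((domain, "negation"), [])
                    ),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
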