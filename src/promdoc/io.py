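"""JSONL serialization for notes, visit metadata, standoff spans and datasets.

One JSON object per line throughout:

* raw notes: ``{note_id, visit_id, patient_id, service_date, facility_id,
  author_role, text}``;
* prepared corpus: ``{visit: {...}, note: {...}}`` pairs whose body offsets
  are stable across a round-trip;
* standoff annotation: ``{visit_id, spans: [{start, end, prom_id, source}]}``;
* labeled datasets: ``{visit_id, text, label}``.
"""

from __future__ import annotations

import json
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

from promdoc.corpus_prep import ClinicNote, RawNote, VisitCategory, VisitRecord
from promdoc.evaluation import LabeledNote
from promdoc.matcher import NoteResult, PromSpan

__all__ = [
    "read_raw_notes",
    "write_corpus",
    "read_corpus",
    "write_standoff",
    "read_standoff",
    "write_dataset",
    "read_dataset",
]


def _lines(path: str | Path) -> Iterable[dict]:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield json.loads(line)


def _dump(path: str | Path, rows: Iterable[dict]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for row in rows:
            fh.write(json.dumps(row, ensure_ascii=False) + "\n")


def read_raw_notes(path: str | Path) -> list[RawNote]:
    return [
        RawNote(
            note_id=r["note_id"],
            visit_id=r["visit_id"],
            patient_id=r["patient_id"],
            service_date=date.fromisoformat(r["service_date"]),
            facility_id=r["facility_id"],
            author_role=r.get("author_role", ""),
            text=r["text"],
        )
        for r in _lines(path)
    ]


def _visit_to_dict(v: VisitRecord) -> dict:
    return {
        "visit_id": v.visit_id,
        "patient_id": v.patient_id,
        "service_date": v.service_date.isoformat(),
        "facility_id": v.facility_id,
        "consult_date": v.consult_date.isoformat(),
        "visit_index": v.visit_index,
        "visit_total": v.visit_total,
        "days_since_prev": v.days_since_prev,
        "days_to_next": v.days_to_next,
        "category": v.category.value if v.category else None,
    }


def _visit_from_dict(d: dict) -> VisitRecord:
    return VisitRecord(
        visit_id=d["visit_id"],
        patient_id=d["patient_id"],
        service_date=date.fromisoformat(d["service_date"]),
        facility_id=d["facility_id"],
        consult_date=date.fromisoformat(d["consult_date"]),
        visit_index=d["visit_index"],
        visit_total=d["visit_total"],
        days_since_prev=d.get("days_since_prev"),
        days_to_next=d.get("days_to_next"),
        category=VisitCategory(d["category"]) if d.get("category") else None,
    )


def write_corpus(
    path: str | Path, corpus: Sequence[tuple[ClinicNote, VisitRecord]]
) -> None:
    _dump(
        path,
        (
            {
                "visit": _visit_to_dict(rec),
                "note": {
                    "header": note.header,
                    "body": note.body,
                    "source_note_ids": list(note.source_note_ids),
                },
            }
            for note, rec in corpus
        ),
    )


def read_corpus(path: str | Path) -> list[tuple[ClinicNote, VisitRecord]]:
    out = []
    for r in _lines(path):
        rec = _visit_from_dict(r["visit"])
        out.append(
            (
                ClinicNote(
                    visit_id=rec.visit_id,
                    patient_id=rec.patient_id,
                    service_date=rec.service_date,
                    facility_id=rec.facility_id,
                    header=r["note"]["header"],
                    body=r["note"]["body"],
                    source_note_ids=tuple(r["note"]["source_note_ids"]),
                ),
                rec,
            )
        )
    return out


def write_standoff(path: str | Path, results: Sequence[NoteResult]) -> None:
    _dump(
        path,
        (
            {
                "visit_id": r.visit_id,
                "prom_positive": r.prom_positive,
                "spans": [
                    {
                        "start": s.start,
                        "end": s.end,
                        "prom_id": s.prom_id,
                        "source": s.source,
                        "surface": s.surface,
                        "section_label": s.section_label,
                        "match_kind": s.match_kind,
                    }
                    for s in r.spans
                ],
            }
            for r in results
        ),
    )


def read_standoff(path: str | Path) -> dict[str, list[PromSpan]]:
    out: dict[str, list[PromSpan]] = {}
    for r in _lines(path):
        out[r["visit_id"]] = [
            PromSpan(
                start=s["start"],
                end=s["end"],
                surface=s.get("surface", ""),
                prom_id=s["prom_id"],
                source=s.get("source", "human"),
                section_label=s.get("section_label"),
                match_kind=s.get("match_kind", "alias"),
            )
            for s in r["spans"]
        ]
    return out


def write_dataset(path: str | Path, items: Sequence[LabeledNote]) -> None:
    _dump(
        path,
        ({"visit_id": i.visit_id, "text": i.text, "label": i.label} for i in items),
    )


def read_dataset(path: str | Path) -> list[LabeledNote]:
    return [
        LabeledNote(visit_id=r["visit_id"], text=r["text"], label=bool(r["label"]))
        for r in _lines(path)
    ]
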