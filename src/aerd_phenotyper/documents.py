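"""Clinical document containers and the line-delimited notes format.

A document is an ordered list of section spans over its raw text. Notes are
persisted one JSON record per line with fields ``patient_id``, ``doc_date``
(ISO 8601) and ``sections`` (ordered list of ``{"header", "text"}``).
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field

#: header name assigned to text that precedes any recognized section header
UNLABELED = "UNLABELED"


@dataclass
class SectionSpan:
    """One section of a document.

    ``char_start``/``char_end`` delimit the whole region in the raw document
    (header line included, 0-based half-open); ``body_start`` is the offset
    at which ``text`` — the body after the header line — begins.
    """

    header: str
    text: str
    char_start: int
    char_end: int
    body_start: int = 0

    def __post_init__(self) -> None:
        if self.char_start >= self.char_end:
            raise ValueError("section span must be non-empty (char_start < char_end)")


@dataclass
class ClinicalDocument:
    patient_id: str
    doc_date: dt.date
    sections: list[SectionSpan] = field(default_factory=list)

    def to_text(self) -> str:
        """Reconstruct the raw note: ``Header:`` line then body per section."""
        parts = []
        for s in self.sections:
            if s.header != UNLABELED:
                parts.append(f"{s.header}:\n")
            parts.append(s.text if s.text.endswith("\n") else s.text + "\n")
        return "".join(parts)

    @classmethod
    def from_section_texts(
        cls, patient_id: str, doc_date: dt.date, sections: list[tuple[str, str]]
    ) -> "ClinicalDocument":
        """Build a document from (header, body) pairs, computing offsets."""
        spans: list[SectionSpan] = []
        pos = 0
        for header, body in sections:
            start = pos
            if header != UNLABELED:
                pos += len(header) + 2  # "Header:" + newline
            body_start = pos
            if not body.endswith("\n"):
                body = body + "\n"
            pos += len(body)
            spans.append(SectionSpan(header, body, start, pos, body_start))
        return cls(patient_id, doc_date, spans)


def parse_date(value: str) -> dt.date:
    return dt.date.fromisoformat(value)


def write_notes(documents: list[ClinicalDocument], path) -> None:
    with open(path, "w") as fh:
        for doc in documents:
            rec = {
                "patient_id": doc.patient_id,
                "doc_date": doc.doc_date.isoformat(),
                "sections": [{"header": s.header, "text": s.text} for s in doc.sections],
            }
            fh.write(json.dumps(rec) + "\n")


def read_notes(path) -> list[ClinicalDocument]:
    docs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            docs.append(
                ClinicalDocument.from_section_texts(
                    rec["patient_id"],
                    parse_date(rec["doc_date"]),
                    [(s["header"], s["text"]) for s in rec["sections"]],
                )
            )
    return docs
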