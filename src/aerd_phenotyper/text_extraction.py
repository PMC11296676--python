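"""Lexicon-based feature extraction from sectioned clinical notes.

Three stages mirror a dictionary tagger: (1) segment raw note text into
sections on recognized ``Header:`` lines, (2) scan each section for lexicon
phrase hits (case-insensitive, word-boundary anchored, leftmost-longest
across overlapping candidates) plus numeric urine-LTE4 lab sentences, and
(3) keep only mentions that fall in whitelisted sections — the note regions
in which an assertion of the feature is taken at face value.
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
import re
from dataclasses import dataclass

from .documents import UNLABELED, ClinicalDocument, SectionSpan, parse_date
from .features import FEATURES, validate_feature
from .lexicon import FeatureLexicon

logger = logging.getLogger(__name__)

#: sections in which an extracted feature counts as valid
SECTION_WHITELIST: tuple[str, ...] = (
    "History of Present Illness",
    "Allergies",
    "Past Medical/Surgical History",
    "Impression/Report/Plan",
    "Diagnosis",
    "Principal Diagnosis",
    "Secondary Diagnoses",
    "Post Procedure Diagnosis",
)

#: non-whitelisted sections used by the synthetic generator as decoy targets
DISTRACTOR_SECTIONS: tuple[str, ...] = (
    "Family History",
    "Social History",
    "Medications",
    "Review of Systems",
    "Chief Complaint",
)

SECTION_VOCABULARY: tuple[str, ...] = SECTION_WHITELIST + DISTRACTOR_SECTIONS


@dataclass(frozen=True)
class FeatureMention:
    """One detected feature hit, with document-level character offsets."""

    patient_id: str
    feature: str
    section: str
    doc_date: dt.date
    start: int
    end: int
    matched_pattern: str

    def __post_init__(self) -> None:
        validate_feature(self.feature)
        if self.start >= self.end:
            raise ValueError("mention span must be non-empty")


def segment_sections(
    raw_text: str, section_vocabulary: list[str] | tuple[str, ...] = SECTION_VOCABULARY
) -> list[SectionSpan]:
    """Partition ``raw_text`` into section spans.

    A header is a line whose stripped content equals a vocabulary name
    followed by ``:`` (case-insensitive). Every character of the input
    belongs to exactly one span; text before the first header becomes an
    UNLABELED span. Degenerate input yields a single UNLABELED span.
    """
    headers = {name.lower() + ":": name for name in section_vocabulary}
    # split keeping line boundaries so offsets stay exact
    lines = raw_text.splitlines(keepends=True)
    if not lines:
        return [SectionSpan(UNLABELED, raw_text or " ", 0, max(len(raw_text), 1), 0)]

    boundaries: list[tuple[int, str, int]] = []  # (line_start, canonical name, body_start)
    pos = 0
    for line in lines:
        name = headers.get(line.strip().lower())
        if name is not None:
            boundaries.append((pos, name, pos + len(line)))
        pos += len(line)

    spans: list[SectionSpan] = []
    if not boundaries or boundaries[0][0] > 0:
        end = boundaries[0][0] if boundaries else len(raw_text)
        spans.append(SectionSpan(UNLABELED, raw_text[:end], 0, end, 0))
    for i, (start, name, body_start) in enumerate(boundaries):
        end = boundaries[i + 1][0] if i + 1 < len(boundaries) else len(raw_text)
        spans.append(SectionSpan(name, raw_text[body_start:end], start, end, body_start))
    return spans


def _compile_phrase_pattern(phrase: str) -> re.Pattern:
    # literal phrase, flexible internal whitespace, word-boundary anchored
    parts = [re.escape(tok) for tok in phrase.split()]
    body = r"\s+".join(parts)
    return re.compile(rf"(?<!\w){body}(?!\w)", re.IGNORECASE)


def _candidate_matches(section: SectionSpan, lexicon: FeatureLexicon):
    """All raw pattern hits in a section (before overlap resolution)."""
    text = section.text
    cands: list[tuple[int, int, str, str]] = []  # (start, end, feature, pattern)
    for feature in FEATURES:
        if feature == "LAB":
            continue
        for phrase in lexicon.all_phrases(feature):
            for m in _compile_phrase_pattern(phrase).finditer(text):
                cands.append((m.start(), m.end(), feature, m.group(0)))
    lab_re = re.compile(lexicon.lab_pattern, re.IGNORECASE)
    for m in lab_re.finditer(text):
        try:
            value = float(m.group(1))
        except ValueError:
            logger.warning("unparseable urine LTE4 value %r; sentence skipped", m.group(1))
            continue
        if value > lexicon.lab_threshold:  # strictly greater than 104 pg/mg
            cands.append((m.start(), m.end(), "LAB", m.group(0)))
    return cands


def _resolve_overlaps(cands: list[tuple[int, int, str, str]]):
    """Leftmost-longest selection over all features.

    Overlapping candidates are resolved globally so that a phrase embedded
    in a longer phrase (e.g. an allergy phrase inside an explicit
    no-allergy statement) yields only the longer mention.
    """
    chosen: list[tuple[int, int, str, str]] = []
    last_end = -1
    for cand in sorted(cands, key=lambda c: (c[0], -(c[1] - c[0]))):
        if cand[0] >= last_end:
            chosen.append(cand)
            last_end = cand[1]
    return chosen


def find_mentions(doc: ClinicalDocument, lexicon: FeatureLexicon) -> list[FeatureMention]:
    """Scan every section of an already-segmented document for lexicon hits.

    Matching is a pure function of (document, lexicon): case-insensitive on
    word boundaries, one mention per non-overlapping occurrence, LAB emitted
    only for values strictly above the elevation threshold.
    """
    mentions: list[FeatureMention] = []
    for section in doc.sections:
        for start, end, feature, pattern in _resolve_overlaps(
            _candidate_matches(section, lexicon)
        ):
            mentions.append(
                FeatureMention(
                    patient_id=doc.patient_id,
                    feature=feature,
                    section=section.header,
                    doc_date=doc.doc_date,
                    start=section.body_start + start,
                    end=section.body_start + end,
                    matched_pattern=pattern,
                )
            )
    return mentions


def filter_valid_sections(
    mentions: list[FeatureMention],
    whitelist: list[str] | tuple[str, ...] = SECTION_WHITELIST,
) -> list[FeatureMention]:
    """Keep only mentions located in whitelisted sections (order preserved)."""
    allowed = set(whitelist)
    return [m for m in mentions if m.section in allowed]


# -- mention table I/O ----------------------------------------------------

MENTION_COLUMNS = ("patient_id", "feature", "section", "date", "start", "end", "pattern")


def write_mentions(mentions: list[FeatureMention], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(MENTION_COLUMNS)
        for m in mentions:
            w.writerow(
                [m.patient_id, m.feature, m.section, m.doc_date.isoformat(), m.start, m.end, m.matched_pattern]
            )


def read_mentions(path) -> list[FeatureMention]:
    out = []
    with open(path, newline="") as fh:
        r = csv.DictReader(fh, delimiter="\t")
        for row in r:
            out.append(
                FeatureMention(
                    patient_id=row["patient_id"],
                    feature=row["feature"],
                    section=row["section"],
                    doc_date=parse_date(row["date"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    matched_pattern=row["pattern"],
                )
            )
    return out


def extract_corpus(
    documents: list[ClinicalDocument],
    lexicon: FeatureLexicon,
    whitelist: list[str] | tuple[str, ...] = SECTION_WHITELIST,
) -> list[FeatureMention]:
    """find_mentions + section filter over a whole corpus."""
    mentions: list[FeatureMention] = []
    for doc in documents:
        mentions.extend(find_mentions(doc, lexicon))
    return filter_valid_sections(mentions, whitelist)
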