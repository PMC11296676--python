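"""Feature lexicons: the surface patterns matched in clinical text.

Each of the seven features carries a list of canonical phrases plus a list
of typo/abbreviation variants; matching treats both alike. The LAB feature
is special: it is not a phrase but a sentence pattern that captures a
numeric urinary leukotriene E4 value, and a mention is emitted only when
the captured value is strictly greater than the elevation threshold of
104 pg/mg creatinine.

The default lexicon shipped here is documented, replaceable data — the
pipeline is reproducible with any lexicon supplied as a YAML config.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import yaml

from .features import FEATURES

#: urine LTE4 value below which a lab sentence does NOT count as elevated
LAB_THRESHOLD_PG_MG = 104.0

#: captures the numeric value of a urinary leukotriene E4 lab sentence
DEFAULT_LAB_PATTERN = (
    r"\burin(?:e|ary)\s+(?:leukotriene\s+E4|LTE4)\s+(?:level\s+)?"
    r"(?:was|is|of|measured|at|[:=])?\s*"
    r"(\S+)\s*pg\s*/\s*mg\s+creatinine"
)

_DEFAULT_PATTERNS: dict[str, dict[str, list[str]]] = {
    "AERD": {
        "patterns": [
            "aspirin-exacerbated respiratory disease",
            "aspirin exacerbated respiratory disease",
            "AERD",
            "aspirin triad",
            "Samter's triad",
            "aspirin-induced asthma",
        ],
        "variants": ["Samters triad", "asa exacerbated respiratory disease"],
    },
    "ASTHMA": {
        "patterns": ["asthma", "asthmatic", "bronchial asthma"],
        "variants": ["athsma", "asthama"],
    },
    "NSAID_ALLERGY": {
        "patterns": [
            "NSAID allergy",
            "aspirin allergy",
            "allergic to aspirin",
            "allergic to NSAIDs",
            "respiratory reaction to aspirin",
            "ASA allergy",
        ],
        "variants": ["nsaid alergy", "aspirin alergy"],
    },
    "NASAL_POLYPS": {
        "patterns": ["nasal polyps", "nasal polyposis", "nasal polyp"],
        "variants": ["nasal polpys", "nasal poyps"],
    },
    "CHRONIC_SINUSITIS": {
        "patterns": [
            "chronic sinusitis",
            "chronic rhinosinusitis",
            "chronic sinus disease",
            "CRS",
        ],
        "variants": ["chronic sinusitus", "chronic rhino sinusitis"],
    },
    # LAB is value-pattern based; phrase lists stay empty.
    "LAB": {"patterns": [], "variants": []},
    "NO_NSAID_ALLERGY": {
        "patterns": [
            "no known NSAID allergy",
            "no NSAID allergy",
            "no history of NSAID allergy",
            "tolerates aspirin without reaction",
            "denies aspirin allergy",
            "no specific history of NSAID allergy",
        ],
        "variants": ["no known nsaid alergy", "tolerates asa without reaction"],
    },
}


@dataclass
class FeatureLexicon:
    """Surface patterns per feature id, plus the LAB value pattern.

    ``patterns`` maps each feature id to ``{"patterns": [...], "variants": [...]}``.
    ``lab_pattern`` is a regex with one capture group for the numeric value;
    ``lab_threshold`` is the strict lower bound for an elevated result.
    """

    patterns: dict[str, dict[str, list[str]]] = field(
        default_factory=lambda: {k: {s: list(v[s]) for s in v} for k, v in _DEFAULT_PATTERNS.items()}
    )
    lab_pattern: str = DEFAULT_LAB_PATTERN
    lab_threshold: float = LAB_THRESHOLD_PG_MG

    def __post_init__(self) -> None:
        if set(self.patterns) != set(FEATURES):
            raise ValueError(
                f"lexicon must define exactly the features {FEATURES}, got {sorted(self.patterns)}"
            )
        for feat, groups in self.patterns.items():
            for kind in ("patterns", "variants"):
                for p in groups.get(kind, []):
                    if not p or not p.strip():
                        raise ValueError(f"empty pattern for feature {feat}")
        if not self.lab_pattern:
            raise ValueError("lab_pattern must be non-empty")
        re.compile(self.lab_pattern)  # fail fast on a bad regex

    def all_phrases(self, feature: str) -> list[str]:
        g = self.patterns[feature]
        return list(g.get("patterns", [])) + list(g.get("variants", []))

    def canonical_phrases(self, feature: str) -> list[str]:
        return list(self.patterns[feature].get("patterns", []))

    def variant_phrases(self, feature: str) -> list[str]:
        return list(self.patterns[feature].get("variants", []))

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "features": self.patterns,
            "lab_pattern": self.lab_pattern,
            "lab_threshold": self.lab_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureLexicon":
        return cls(
            patterns=d["features"],
            lab_pattern=d.get("lab_pattern", DEFAULT_LAB_PATTERN),
            lab_threshold=float(d.get("lab_threshold", LAB_THRESHOLD_PG_MG)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FeatureLexicon":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_lexicon() -> FeatureLexicon:
    """The documented default lexicon (replaceable data, not code)."""
    return FeatureLexicon()
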