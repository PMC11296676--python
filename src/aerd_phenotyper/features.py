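"""Canonical AERD feature identifiers.

Seven clinical features are tracked per patient: a prior AERD diagnosis,
asthma, a documented respiratory reaction to an NSAID, nasal polyps, chronic
sinusitis, an elevated urinary leukotriene E4 level (LAB), and an explicit
statement that the patient has no NSAID allergy to date. The tuple order
below is the fixed column order of every feature matrix the package writes.
"""

FEATURES: tuple[str, ...] = (
    "AERD",
    "ASTHMA",
    "NSAID_ALLERGY",
    "NASAL_POLYPS",
    "CHRONIC_SINUSITIS",
    "LAB",
    "NO_NSAID_ALLERGY",
)

FEATURE_INDEX: dict[str, int] = {f: i for i, f in enumerate(FEATURES)}


def validate_feature(feature: str) -> str:
    if feature not in FEATURE_INDEX:
        raise ValueError(f"unknown feature id: {feature!r}; expected one of {FEATURES}")
    return feature
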