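"""Ground-truthed synthetic clinical note corpora.

The generator emulates the kind of sectioned allergy/immunology notes the
phenotyping pipeline consumes: each patient receives a gold AERD label, a
set of target feature-mention counts planted inside the 5-year lookback
window in whitelisted sections, and decoy mentions planted where the
pipeline must ignore them — in non-whitelisted sections (e.g. "Family
History") or in documents dated more than 5 years before the last visit.
Filler prose is drawn from a fixed pattern-free sentence list so that
extract → aggregate on a generated corpus reproduces the planted counts
exactly, for every patient, as a hard invariant.

Per-class count distributions are truncated geometrics whose class-
conditional presence rates roughly track a specialist-clinic case/control
cohort (cases: frequent prior-AERD, NSAID-reaction and chronic-sinusitis
documentation; controls: sinus/asthma-heavy but with few AERD or
NSAID-reaction mentions). Draws are rejection-matched to the published
rule set so that, at zero label noise, every profile's gold label equals
the rule set's classification of its target counts.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .documents import ClinicalDocument
from .features import FEATURES, validate_feature
from .lexicon import FeatureLexicon, default_lexicon
from .rules_engine import POSITIVE, RuleSet, classify, classify_matrix, default_aerd_ruleset
from .text_extraction import DISTRACTOR_SECTIONS, SECTION_WHITELIST

#: largest plantable mention count per feature
MAX_COUNT = 12

#: reference "today" used to place last-visit dates
BASE_DATE = dt.date(2022, 3, 1)

WINDOW_DAYS = int(5 * 365.25)  # 1826

#: filler sentences, checked to contain no lexicon pattern
FILLER_SENTENCES = (
    "Patient returned for routine follow up today.",
    "Vital signs were stable and reviewed in detail.",
    "Continues current management without change.",
    "Discussed goals of care and the next appointment.",
    "Sleep and appetite were reported as adequate.",
    "No acute concerns were raised during the visit.",
    "Counseled regarding lifestyle and medication adherence.",
)


@dataclass(frozen=True)
class Plant:
    """One mention to render: feature, target section, variant flag, and —
    for LAB — the numeric urine LTE4 value to print."""

    feature: str
    section: str
    variant: bool = False
    value: float | None = None

    def __post_init__(self) -> None:
        validate_feature(self.feature)


@dataclass(frozen=True)
class CountDistribution:
    """Truncated geometric over 0..max_count: P(k) ∝ (1-p)^k."""

    p: float
    max_count: int = MAX_COUNT

    def __post_init__(self) -> None:
        if not 0 < self.p <= 1:
            raise ValueError("geometric parameter p must be in (0, 1]")

    def pmf(self) -> np.ndarray:
        w = (1 - self.p) ** np.arange(self.max_count + 1)
        return w / w.sum()

    def sample(self, rng: np.random.Generator, size: int | None = None):
        return rng.choice(self.max_count + 1, size=size, p=self.pmf())


def default_count_distributions() -> dict[int, dict[str, CountDistribution]]:
    """Class-conditional (1=AERD, 0=control) per-feature count models."""
    pos = {
        "AERD": 0.12,
        "ASTHMA": 0.04,
        "NSAID_ALLERGY": 0.15,
        "NASAL_POLYPS": 0.10,
        "CHRONIC_SINUSITIS": 0.08,
        "LAB": 0.45,
        "NO_NSAID_ALLERGY": 0.75,
    }
    neg = {
        "AERD": 0.85,
        "ASTHMA": 0.07,
        "NSAID_ALLERGY": 0.80,
        "NASAL_POLYPS": 0.25,
        "CHRONIC_SINUSITIS": 0.15,
        "LAB": 0.60,
        "NO_NSAID_ALLERGY": 0.45,
    }
    return {
        1: {f: CountDistribution(p) for f, p in pos.items()},
        0: {f: CountDistribution(p) for f, p in neg.items()},
    }


@dataclass
class PatientProfile:
    patient_id: str
    aerd_label: int
    target_counts: dict[str, int]
    decoy_counts: dict[str, int]
    last_visit_date: dt.date
    n_documents: int

    def __post_init__(self) -> None:
        for counts in (self.target_counts, self.decoy_counts):
            for f, v in counts.items():
                validate_feature(f)
                if v < 0:
                    raise ValueError("counts must be non-negative")
        if self.n_documents < 1:
            raise ValueError("n_documents must be >= 1")
        self.target_counts = {f: int(self.target_counts.get(f, 0)) for f in FEATURES}
        self.decoy_counts = {f: int(self.decoy_counts.get(f, 0)) for f in FEATURES}


@dataclass
class CorpusConfig:
    n_positive: int = 100
    n_negative: int = 100
    label_noise_rate: float = 0.0
    count_distributions: dict[int, dict[str, CountDistribution]] = field(
        default_factory=default_count_distributions
    )
    typo_rate: float = 0.10
    #: per-feature probability of planting decoy mentions for a patient
    decoy_rate: float = 0.25
    seed: int = 20

    def __post_init__(self) -> None:
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValueError("cohort sizes must be non-negative")
        for name in ("label_noise_rate", "typo_rate", "decoy_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


# -- rendering ------------------------------------------------------------

_MENTION_TEMPLATES = (
    "Assessment documents {phrase} during this visit.",
    "Record review confirms {phrase} as noted previously.",
)

_LAB_TEMPLATE = "Urine LTE4 level was {value} pg/mg creatinine."


def _mention_sentence(
    plant: Plant, lexicon: FeatureLexicon, rng: np.random.Generator | None
) -> str:
    if plant.feature == "LAB":
        value = plant.value if plant.value is not None else 150
        v = int(value) if float(value).is_integer() else value
        return _LAB_TEMPLATE.format(value=v)
    phrases = (
        lexicon.variant_phrases(plant.feature)
        if plant.variant and lexicon.variant_phrases(plant.feature)
        else lexicon.canonical_phrases(plant.feature)
    )
    if not phrases:
        raise ValueError(f"lexicon has no phrases for feature {plant.feature}")
    pi = int(rng.integers(len(phrases))) if rng is not None else 0
    ti = int(rng.integers(len(_MENTION_TEMPLATES))) if rng is not None else 0
    return _MENTION_TEMPLATES[ti].format(phrase=phrases[pi])


def render_document(
    profile: PatientProfile,
    date: dt.date,
    mentions_to_plant: list[Plant],
    lexicon: FeatureLexicon | None = None,
    rng: np.random.Generator | None = None,
) -> ClinicalDocument:
    """Render one sectioned note containing exactly the requested mentions.

    Each plant becomes one sentence embedding one lexicon pattern inside the
    named section; all other prose is filler with no lexicon hit. A filler
    section is always present so that empty plant lists still produce a
    well-formed note.
    """
    vocab = set(SECTION_WHITELIST) | set(DISTRACTOR_SECTIONS)
    for p in mentions_to_plant:
        if p.section not in vocab:
            raise ValueError(f"unknown section name: {p.section!r}")

    bodies: dict[str, list[str]] = {}

    def filler() -> str:
        i = int(rng.integers(len(FILLER_SENTENCES))) if rng is not None else 0
        return FILLER_SENTENCES[i]

    filler_section = "History of Present Illness"
    bodies.setdefault(filler_section, []).append(filler())
    for plant in mentions_to_plant:
        bodies.setdefault(plant.section, [])
    for plant in mentions_to_plant:
        bodies[plant.section].append(_mention_sentence(plant, lexicon or default_lexicon(), rng))
    for section in bodies:
        bodies[section].append(filler())

    ordered = [s for s in SECTION_WHITELIST + DISTRACTOR_SECTIONS if s in bodies]
    return ClinicalDocument.from_section_texts(
        profile.patient_id, date, [(s, "\n".join(bodies[s])) for s in ordered]
    )


# -- cohort generation ----------------------------------------------------

def _draw_counts(
    rng: np.random.Generator,
    dists: dict[str, CountDistribution],
    want_positive: bool,
    ruleset: RuleSet,
    max_tries: int = 200,
) -> dict[str, int]:
    """Sample a count vector whose rule-set classification matches the
    class it was drawn for (rejection sampling with a deterministic
    fallback)."""
    for _ in range(max_tries):
        counts = {f: int(dists[f].sample(rng)) for f in FEATURES}
        label, _rid = classify(counts, ruleset)
        if (label == POSITIVE) == want_positive:
            return counts
    fallback = dict.fromkeys(FEATURES, 0)
    if want_positive:
        fallback.update({"AERD": 5, "NSAID_ALLERGY": 3, "CHRONIC_SINUSITIS": 10})
    return fallback


def generate_cohort(
    config: CorpusConfig,
    lexicon: FeatureLexicon | None = None,
    ruleset: RuleSet | None = None,
) -> tuple[list[ClinicalDocument], list[PatientProfile]]:
    """Generate a labelled cohort of sectioned notes plus its ground truth.

    Deterministic for a fixed ``config.seed``. Target mentions land in
    whitelisted sections of documents dated within the 5-year window ending
    at the last visit; decoys land either in non-whitelisted sections
    (in-window) or in whitelisted sections of documents strictly older than
    the window, exercising both exclusion paths.
    """
    lexicon = lexicon or default_lexicon()
    ruleset = ruleset or default_aerd_ruleset()
    rng = np.random.default_rng(config.seed)

    profiles: list[PatientProfile] = []
    documents: list[ClinicalDocument] = []
    n_total = config.n_positive + config.n_negative

    for i in range(n_total):
        intended = 1 if i < config.n_positive else 0
        pid = f"P{i:04d}"
        noisy = rng.random() < config.label_noise_rate
        dist_class = 1 - intended if noisy else intended
        target = _draw_counts(rng, config.count_distributions[dist_class], dist_class == 1, ruleset)

        decoy = dict.fromkeys(FEATURES, 0)
        for f in FEATURES:
            if rng.random() < config.decoy_rate:
                decoy[f] = int(rng.integers(1, 3))

        last_visit = BASE_DATE - dt.timedelta(days=int(rng.integers(0, 90)))
        n_docs = int(rng.integers(2, 7))
        profile = PatientProfile(pid, intended, target, decoy, last_visit, n_docs)
        profiles.append(profile)

        in_window_dates = [last_visit] + [
            last_visit - dt.timedelta(days=int(rng.integers(1, WINDOW_DAYS - 30)))
            for _ in range(n_docs - 1)
        ]

        plants_by_date: dict[dt.date, list[Plant]] = {d: [] for d in in_window_dates}

        def add_plant(date: dt.date, plant: Plant) -> None:
            plants_by_date.setdefault(date, []).append(plant)

        for f in FEATURES:
            for _ in range(profile.target_counts[f]):
                date = in_window_dates[int(rng.integers(len(in_window_dates)))]
                section = SECTION_WHITELIST[int(rng.integers(len(SECTION_WHITELIST)))]
                variant = bool(rng.random() < config.typo_rate)
                value = int(rng.integers(110, 400)) if f == "LAB" else None
                add_plant(date, Plant(f, section, variant, value))

        for f in FEATURES:
            for _ in range(profile.decoy_counts[f]):
                value = int(rng.integers(110, 400)) if f == "LAB" else None
                if rng.random() < 0.5:
                    # in-window but in a section the filter must reject
                    date = in_window_dates[int(rng.integers(len(in_window_dates)))]
                    section = DISTRACTOR_SECTIONS[int(rng.integers(len(DISTRACTOR_SECTIONS)))]
                else:
                    # whitelisted section but strictly outside the window
                    date = last_visit - dt.timedelta(days=int(rng.integers(WINDOW_DAYS + 2, WINDOW_DAYS + 700)))
                    section = SECTION_WHITELIST[int(rng.integers(len(SECTION_WHITELIST)))]
                add_plant(date, Plant(f, section, False, value))

        # occasionally a non-elevated lab sentence: present in text, never a mention
        if rng.random() < 0.3:
            date = in_window_dates[int(rng.integers(len(in_window_dates)))]
            add_plant(date, Plant("LAB", "Impression/Report/Plan", False, int(rng.integers(40, 105))))

        for date in sorted(plants_by_date):
            documents.append(render_document(profile, date, plants_by_date[date], lexicon, rng))

    return documents, profiles


# -- labelled count sampling (no text) ------------------------------------

def sample_cohort_counts(
    n_positive: int,
    n_negative: int,
    label_noise_rate: float = 0.0,
    seed: int = 20,
    count_distributions: dict[int, dict[str, CountDistribution]] | None = None,
    ruleset: RuleSet | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Class-conditional count vectors with gold labels, no note text.

    Same count semantics as :func:`generate_cohort` (rejection-matched
    class-conditional draws; with probability ``label_noise_rate`` a
    patient's counts come from the opposite class's distributions while
    the gold label keeps the intended class), for experiments that need
    only the aggregated feature matrix.
    """
    if n_positive < 0 or n_negative < 0:
        raise ValueError("cohort sizes must be non-negative")
    if not 0 <= label_noise_rate <= 1:
        raise ValueError("label_noise_rate must be in [0, 1]")
    dists = count_distributions or default_count_distributions()
    ruleset = ruleset or default_aerd_ruleset()
    rng = np.random.default_rng(seed)
    X, y = [], []
    for i in range(n_positive + n_negative):
        intended = 1 if i < n_positive else 0
        cls = 1 - intended if rng.random() < label_noise_rate else intended
        counts = _draw_counts(rng, dists[cls], cls == 1, ruleset)
        X.append([counts[f] for f in FEATURES])
        y.append(intended)
    return np.asarray(X, dtype=float), np.asarray(y, dtype=int)



def uniform_labelled_counts(
    n: int, seed: int, grid_max: int = MAX_COUNT, ruleset: RuleSet | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform integer count vectors in [0..grid_max]^7 labelled by a rule
    set — count data whose ranges span every decision threshold."""
    rng = np.random.default_rng(seed)
    X = rng.integers(0, grid_max + 1, size=(n, len(FEATURES)))
    y, _ = classify_matrix(X, ruleset or default_aerd_ruleset())
    return X, y


# -- ground-truth table I/O -----------------------------------------------

def write_truth(profiles: list[PatientProfile], path) -> None:
    rows = [
        {"patient_id": p.patient_id, "label": p.aerd_label, **{f: p.target_counts[f] for f in FEATURES}}
        for p in profiles
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="patient_id")
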