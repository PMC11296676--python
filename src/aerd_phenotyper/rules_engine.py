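"""Sequential rule sets: ordered threshold rules derived from decision trees.

A sequential rule is a conjunction of (feature, ≤/>, threshold) conditions
with a predicted label; a rule set applies its rules in order and returns
the first match (first-match semantics). The published AERD rule set — nine
rules over prior-AERD-diagnosis, NSAID-allergy, chronic-sinusitis, LAB and
documented-no-NSAID-allergy counts — ships as ``default_aerd_ruleset()``.
Because its nine conjunctions are the leaves of a binary tree, they
partition the count space; the optional fallback label only ever applies to
rule sets that do not cover the space.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import yaml

from .features import FEATURE_INDEX, FEATURES, validate_feature
from .aggregation import PatientFeatureVector

#: sentinel rule id reported when no rule matches and a fallback label exists
OTHERS = "OTHERS"

POSITIVE = "Yes"
NEGATIVE = "No"


class Comparator(str, enum.Enum):
    LE = "<="
    GT = ">"


@dataclass(frozen=True)
class RuleCondition:
    feature: str
    comparator: Comparator
    threshold: float

    def __post_init__(self) -> None:
        validate_feature(self.feature)
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def holds(self, value: float) -> bool:
        if self.comparator is Comparator.LE:
            return value <= self.threshold
        return value > self.threshold

    def __str__(self) -> str:
        return f"{self.feature}{self.comparator.value}{self.threshold}"


@dataclass
class SequentialRule:
    rule_id: int
    conditions: list[RuleCondition]
    predicted_label: str  # POSITIVE or NEGATIVE

    def __post_init__(self) -> None:
        if self.predicted_label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be {POSITIVE!r} or {NEGATIVE!r}")

    def matches(self, counts: dict[str, float]) -> bool:
        return all(c.holds(counts[c.feature]) for c in self.conditions)


@dataclass
class RuleSet:
    rules: list[SequentialRule]
    fallback_label: str | None = None

    def __post_init__(self) -> None:
        ids = [r.rule_id for r in self.rules]
        if len(set(ids)) != len(ids):
            raise ValueError("rule ids must be unique")

    # -- serialization -----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "rules": [
                {
                    "id": r.rule_id,
                    "conditions": [
                        {"feature": c.feature, "comparator": c.comparator.value, "threshold": c.threshold}
                        for c in r.conditions
                    ],
                    "label": r.predicted_label,
                }
                for r in self.rules
            ],
            "fallback_label": self.fallback_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RuleSet":
        rules = [
            SequentialRule(
                rule_id=r["id"],
                conditions=[
                    RuleCondition(c["feature"], Comparator(c["comparator"]), float(c["threshold"]))
                    for c in r["conditions"]
                ],
                predicted_label=r["label"],
            )
            for r in d["rules"]
        ]
        return cls(rules=rules, fallback_label=d.get("fallback_label"))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RuleSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _cond(feature: str, comparator: str, threshold: float) -> RuleCondition:
    return RuleCondition(feature, Comparator(comparator), threshold)


def default_aerd_ruleset() -> RuleSet:
    """The published nine-rule AERD classifier.

    Thresholds are mention counts; e.g. rule 6 reads: prior-AERD count
    ≤ 3.5 and NSAID-allergy count > 2.5 and chronic-sinusitis count > 9.0
    → AERD-positive. The explicit rules partition the count space, so the
    fallback ("others") label is unreachable for complete vectors and is
    kept only as a guard.
    """
    A, N, C, L, D = "AERD", "NSAID_ALLERGY", "CHRONIC_SINUSITIS", "LAB", "NO_NSAID_ALLERGY"
    rows = [
        (1, [(A, "<=", 3.5), (N, "<=", 2.5), (C, "<=", 6.5), (D, "<=", 0.5)], NEGATIVE),
        (2, [(A, "<=", 3.5), (N, "<=", 2.5), (C, "<=", 6.5), (D, ">", 0.5)], NEGATIVE),
        (3, [(A, "<=", 3.5), (N, "<=", 2.5), (C, ">", 6.5), (D, "<=", 0.5)], NEGATIVE),
        (4, [(A, "<=", 3.5), (N, "<=", 2.5), (C, ">", 6.5), (D, ">", 0.5)], NEGATIVE),
        (5, [(A, "<=", 3.5), (N, ">", 2.5), (C, "<=", 9.0)], POSITIVE),
        (6, [(A, "<=", 3.5), (N, ">", 2.5), (C, ">", 9.0)], POSITIVE),
        (7, [(A, ">", 3.5), (N, "<=", 1.5), (L, "<=", 0.5)], POSITIVE),
        (8, [(A, ">", 3.5), (N, "<=", 1.5), (L, ">", 0.5)], NEGATIVE),
        (9, [(A, ">", 3.5), (N, ">", 1.5)], POSITIVE),
    ]
    return RuleSet(
        rules=[SequentialRule(i, [_cond(*c) for c in conds], lab) for i, conds, lab in rows],
        fallback_label=POSITIVE,
    )


def classify(
    vector: PatientFeatureVector | dict[str, float], ruleset: RuleSet
) -> tuple[str, int | str]:
    """First-match classification of one feature vector.

    Returns ``(label, matched_rule_id)``; if no rule matches and a fallback
    label is configured, the rule id is the ``OTHERS`` sentinel.
    """
    counts = vector.counts if isinstance(vector, PatientFeatureVector) else vector
    missing = [f for f in FEATURES if f not in counts]
    if missing:
        raise ValueError(f"vector missing features: {missing}")
    for rule in ruleset.rules:
        if rule.matches(counts):
            return rule.predicted_label, rule.rule_id
    if ruleset.fallback_label is not None:
        return ruleset.fallback_label, OTHERS
    raise ValueError("no rule matched and no fallback label configured")


def _rule_mask(rule: SequentialRule, X: np.ndarray) -> np.ndarray:
    mask = np.ones(len(X), dtype=bool)
    for c in rule.conditions:
        col = X[:, FEATURE_INDEX[c.feature]]
        mask &= (col <= c.threshold) if c.comparator is Comparator.LE else (col > c.threshold)
    return mask


def classify_matrix(X: np.ndarray, ruleset: RuleSet) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized first-match classification of an (n × 7) count array.

    Returns ``(labels, rule_ids)`` with labels 1/0 and rule id -1 for
    fallback matches.
    """
    X = np.asarray(X, dtype=float)
    labels = np.full(len(X), -1, dtype=int)
    rule_ids = np.full(len(X), -1, dtype=int)
    unassigned = np.ones(len(X), dtype=bool)
    for rule in ruleset.rules:
        hit = unassigned & _rule_mask(rule, X)
        labels[hit] = 1 if rule.predicted_label == POSITIVE else 0
        rule_ids[hit] = rule.rule_id
        unassigned &= ~hit
    if unassigned.any():
        if ruleset.fallback_label is None:
            raise ValueError("vectors matched no rule and no fallback label configured")
        labels[unassigned] = 1 if ruleset.fallback_label == POSITIVE else 0
    return labels, rule_ids


@dataclass
class CoverageReport:
    """How many grid vectors match 0, exactly 1, or more than 1 rule."""

    n_total: int
    n_zero: int
    n_one: int
    n_multi: int
    exhaustive: bool

    @property
    def is_partition(self) -> bool:
        return self.n_zero == 0 and self.n_multi == 0


def coverage_check(
    ruleset: RuleSet,
    grid_max: int,
    max_vectors: int = 100_000,
    seed: int = 0,
) -> CoverageReport:
    """Check whether the rules partition the integer grid [0..grid_max]^7.

    Enumerates the grid exhaustively when it fits in ``max_vectors``;
    otherwise draws a uniform subsample of ``max_vectors`` grid points
    (seeded). Each vector is tested against every rule independently
    (ignoring rule order), so duplicated or overlapping rules surface as
    multi-matches.
    """
    n_features = len(FEATURES)
    total = (grid_max + 1) ** n_features
    if total <= max_vectors:
        grids = np.meshgrid(*[np.arange(grid_max + 1)] * n_features, indexing="ij")
        X = np.stack([g.ravel() for g in grids], axis=1).astype(float)
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        X = rng.integers(0, grid_max + 1, size=(max_vectors, n_features)).astype(float)
        exhaustive = False
    match_count = np.zeros(len(X), dtype=int)
    for rule in ruleset.rules:
        match_count += _rule_mask(rule, X)
    return CoverageReport(
        n_total=len(X),
        n_zero=int((match_count == 0).sum()),
        n_one=int((match_count == 1).sum()),
        n_multi=int((match_count > 1).sum()),
        exhaustive=exhaustive,
    )
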