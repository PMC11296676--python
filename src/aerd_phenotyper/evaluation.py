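"""Diagnostic-accuracy evaluation: confusion metrics with exact binomial
confidence intervals, ROC/AUC, per-rule audit tables, and feature
prevalence summaries.

Every proportion metric (sensitivity, specificity, PPV, NPV, accuracy) is a
binomial success fraction and is reported in percent with a two-sided
Clopper–Pearson exact 95% interval. AUC is the Mann–Whitney rank statistic
with a seeded stratified-bootstrap interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURES
from .rules_engine import OTHERS, POSITIVE, RuleSet, classify
from .aggregation import PatientFeatureVector


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        t = np.asarray(y_true, dtype=int)
        p = np.asarray(y_pred, dtype=int)
        if t.shape != p.shape:
            raise ValueError("y_true and y_pred must be the same length")
        return cls(
            tp=int(((t == 1) & (p == 1)).sum()),
            fn=int(((t == 1) & (p == 0)).sum()),
            tn=int(((t == 0) & (p == 0)).sum()),
            fp=int(((t == 0) & (p == 1)).sum()),
        )


@dataclass(frozen=True)
class BinomialCI:
    """A binomial proportion on the percent scale with its exact 95% CI."""

    point: float
    lower: float
    upper: float
    successes: int
    trials: int
    level: float = 95.0

    def display(self) -> str:
        return f"{self.point:.2f} ({self.lower:.2f}-{self.upper:.2f})"


def clopper_pearson(successes: int, trials: int, level: float = 95.0) -> BinomialCI:
    """Exact two-sided binomial interval from beta quantiles, in percent.

    The lower endpoint is 0 when ``successes`` is 0 and the upper endpoint
    is 100 when ``successes`` equals ``trials``.
    """
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    if not 0 < level < 100:
        raise ValueError("level must be in (0, 100)")
    alpha = 1.0 - level / 100.0
    lo = 0.0 if successes == 0 else stats.beta.ppf(alpha / 2, successes, trials - successes + 1)
    hi = 1.0 if successes == trials else stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes)
    return BinomialCI(
        point=100.0 * successes / trials,
        lower=100.0 * float(lo),
        upper=100.0 * float(hi),
        successes=successes,
        trials=trials,
        level=level,
    )


@dataclass
class MetricsReport:
    sensitivity: BinomialCI | None
    specificity: BinomialCI | None
    ppv: BinomialCI | None
    npv: BinomialCI | None
    accuracy: BinomialCI | None
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        out = {}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            ci: BinomialCI | None = getattr(self, name)
            out[name] = (
                None
                if ci is None
                else {"point": ci.point, "lower": ci.lower, "upper": ci.upper,
                      "successes": ci.successes, "trials": ci.trials}
            )
        out["auc"] = self.auc
        out["auc_ci"] = list(self.auc_ci) if self.auc_ci else None
        return out

    def display(self) -> str:
        lines = []
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            ci = getattr(self, name)
            lines.append(f"{name:>12}: " + (ci.display() if ci else "undefined"))
        if self.auc is not None:
            s = f"{'auc':>12}: {self.auc:.2f}"
            if self.auc_ci:
                s += f" ({self.auc_ci[0]:.2f}-{self.auc_ci[1]:.2f})"
            lines.append(s)
        return "\n".join(lines)


def confusion_metrics(counts: ConfusionCounts, level: float = 95.0) -> MetricsReport:
    """Sensitivity, specificity, PPV, NPV and accuracy with exact CIs.

    A metric whose denominator is zero is reported as None (undefined),
    never as 0.
    """
    def metric(s: int, n: int) -> BinomialCI | None:
        return None if n == 0 else clopper_pearson(s, n, level)

    return MetricsReport(
        sensitivity=metric(counts.tp, counts.tp + counts.fn),
        specificity=metric(counts.tn, counts.tn + counts.fp),
        ppv=metric(counts.tp, counts.tp + counts.fp),
        npv=metric(counts.tn, counts.tn + counts.fn),
        accuracy=metric(counts.tp + counts.tn, counts.total) if counts.total else None,
    )


def roc_auc(
    scores,
    labels,
    ci: bool = True,
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 95.0,
) -> tuple[float, tuple[float, float] | None]:
    """AUC as the Mann–Whitney statistic (midranks for ties).

    AUC = P(score_pos > score_neg) + 0.5·P(tie), computed from the rank sum
    of the positive class. The CI, when requested, is a seeded stratified
    bootstrap over patients (``n_boot`` resamples, percentile endpoints).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must be the same length")
    pos = y == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute AUC")

    def _auc(sv: np.ndarray, yv: np.ndarray) -> float:
        ranks = stats.rankdata(sv)  # midranks
        r1 = ranks[yv == 1].sum()
        m1 = int((yv == 1).sum())
        m0 = len(yv) - m1
        return (r1 - m1 * (m1 + 1) / 2) / (m1 * m0)

    point = _auc(s, y)
    interval = None
    if ci:
        rng = np.random.default_rng(seed)
        ipos = np.flatnonzero(pos)
        ineg = np.flatnonzero(~pos)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            idx = np.concatenate(
                [rng.choice(ipos, size=n1, replace=True), rng.choice(ineg, size=n0, replace=True)]
            )
            boots[b] = _auc(s[idx], y[idx])
        alpha = 1.0 - level / 100.0
        interval = (
            float(np.quantile(boots, alpha / 2)),
            float(np.quantile(boots, 1 - alpha / 2)),
        )
    return float(point), interval


@dataclass(frozen=True)
class RulePerformanceRow:
    rule_id: int | str
    label: str
    cases: int
    correct: int
    error: int
    confidence: int  # integer percent, 0 when no cases


def rule_performance(
    ruleset: RuleSet,
    vectors: list[PatientFeatureVector],
    gold_labels: list[int],
    expected_rule_assignment: dict[str, int] | None = None,
) -> list[RulePerformanceRow]:
    """Per-rule audit: cases captured, correct and erroneous calls.

    ``cases`` for a rule are the patients expected to be identified by it
    (their entry in ``expected_rule_assignment`` if given, else the rule
    that actually matched). ``correct`` counts cases where the rule fired
    and its predicted label agrees with gold; ``error`` counts cases where
    it fired and disagrees. Confidence = round(100·correct/cases), 0 when
    there are no cases.
    """
    matched = {v.patient_id: classify(v, ruleset) for v in vectors}
    gold = {v.patient_id: int(g) for v, g in zip(vectors, gold_labels)}

    rows = []
    for rule in ruleset.rules:
        if expected_rule_assignment is not None:
            case_ids = [p for p, r in expected_rule_assignment.items() if r == rule.rule_id]
        else:
            case_ids = [p for p, (_, rid) in matched.items() if rid == rule.rule_id]
        correct = error = 0
        for pid in case_ids:
            label, rid = matched[pid]
            if rid != rule.rule_id:
                continue  # diverted to a different rule than expected
            if (label == POSITIVE) == bool(gold[pid]):
                correct += 1
            else:
                error += 1
        cases = len(case_ids)
        conf = int(round_half_up(100.0 * correct / cases)) if cases else 0
        rows.append(
            RulePerformanceRow(rule.rule_id, rule.predicted_label, cases, correct, error, conf)
        )
    return rows


def rule_performance_frame(rows: list[RulePerformanceRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"rule": r.rule_id, "label": r.label, "cases": r.cases,
             "correct": r.correct, "error": r.error, "confidence": r.confidence}
            for r in rows
        ]
    )


def prevalence_report(X: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Per-feature presence summary: patients with a positive count.

    Returns one row per feature with columns ``n`` (patients in whom the
    feature is present) and ``percent`` (of all patients, rounded to the
    nearest integer).
    """
    arr = np.asarray(X, dtype=float)
    n_patients = arr.shape[0]
    present = (arr > 0).sum(axis=0).astype(int)
    percent = [int(round_half_up(100.0 * p / n_patients)) if n_patients else 0 for p in present]
    return pd.DataFrame({"feature": list(FEATURES), "n": present, "percent": percent})
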