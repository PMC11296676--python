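"""Decision-tree derivation of sequential rule sets.

The classifier is a CART decision tree fitted with scikit-learn and
selected by an exhaustive grid search over criterion (gini/entropy),
maximum depth 1–10, minimum samples split 2–10 (step 2), minimum samples
leaf 1–10 and maximum features 1–7 — 7000 configurations — ranked by
in-sample AUC computed from leaf positive-class fractions. After selection
a cutoff sweep scans leaf-probability thresholds 0.1–1.0 (step 0.1),
scoring each by balanced accuracy (sensitivity + specificity)/2, and the
tree is flattened into an ordered sequential rule set: one rule per leaf,
conditions in root-to-leaf order (left child ⇒ ≤ threshold, right ⇒ >),
labelled positive when the leaf positive fraction reaches the cutoff.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURES
from .rules_engine import (
    NEGATIVE,
    POSITIVE,
    Comparator,
    RuleCondition,
    RuleSet,
    SequentialRule,
)

#: tolerance when comparing leaf fractions against a cutoff; leaf fractions
#: and cutoffs are both short decimals whose binary representations can
#: straddle equality
CUTOFF_EPS = 1e-9


@dataclass
class HyperparameterGrid:
    criterion: tuple[str, ...] = ("gini", "entropy")
    max_depth: tuple[int, ...] = tuple(range(1, 11))
    min_samples_split: tuple[int, ...] = (2, 4, 6, 8, 10)
    min_samples_leaf: tuple[int, ...] = tuple(range(1, 11))
    max_features: tuple[int, ...] = tuple(range(1, 8))
    seed: int = 20

    def configurations(self, prefer_deterministic_splits: bool = False) -> list[dict]:
        """All configurations in tie-break order: shallower depth first,
        then lexicographic (criterion, split, leaf, features).

        With ``prefer_deterministic_splits`` the max_features axis is
        ordered descending, so exhaustive split search (all 7 features
        considered at every node) is preferred among otherwise-tied
        configurations; used by cross-validated selection, where the
        deployed tree is a fresh random draw that the fold scores of a
        sub-sampled-feature configuration do not describe.
        """
        mf = sorted(self.max_features, reverse=prefer_deterministic_splits)
        return [
            {
                "max_depth": d,
                "criterion": c,
                "min_samples_split": s,
                "min_samples_leaf": l,
                "max_features": m,
            }
            for d, c, s, l, m in itertools.product(
                sorted(self.max_depth),
                sorted(self.criterion),
                sorted(self.min_samples_split),
                sorted(self.min_samples_leaf),
                mf,
            )
        ]


@dataclass
class TreeSpec:
    """A fitted tree plus the hyperparameters that produced it."""

    criterion: str
    max_depth: int
    min_samples_split: int
    min_samples_leaf: int
    max_features: int
    seed: int
    estimator: DecisionTreeClassifier
    train_auc: float

    @property
    def params(self) -> dict:
        return {
            "criterion": self.criterion,
            "max_depth": self.max_depth,
            "min_samples_split": self.min_samples_split,
            "min_samples_leaf": self.min_samples_leaf,
            "max_features": self.max_features,
            "seed": self.seed,
        }

    def _positive_index(self) -> int:
        classes = list(self.estimator.classes_)
        if 1 not in classes:
            raise ValueError("fitted tree has no positive class")
        return classes.index(1)

    def leaf_scores(self, X) -> np.ndarray:
        """Leaf positive-class training fraction for each row of X."""
        return self.estimator.predict_proba(np.asarray(X, dtype=float))[:, self._positive_index()]


def _rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann–Whitney AUC with midranks (internal model-selection score)."""
    ranks = stats.rankdata(scores)
    n1 = int((y == 1).sum())
    n0 = len(y) - n1
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _swept_balanced_accuracy(scores: np.ndarray, y: np.ndarray) -> float:
    """Best (sensitivity + specificity)/2 over the cutoff sweep 0.1..1.0 —
    the 'single-point-ROC AUC' of the thresholded predictor."""
    pos, neg = y == 1, y == 0
    best = 0.0
    for c in range(1, 11):
        pred = scores >= c / 10 - CUTOFF_EPS
        sens = (pred & pos).sum() / pos.sum()
        spec = (~pred & neg).sum() / neg.sum()
        best = max(best, float((sens + spec) / 2))
    return best


def _selection_score(scores: np.ndarray, y: np.ndarray, selection: str) -> float:
    if selection == "auc":
        return _rank_auc(scores, y)
    if selection == "balanced":
        return _swept_balanced_accuracy(scores, y)
    raise ValueError("selection must be 'auc' or 'balanced'")


def grid_search_cart(
    X,
    y,
    grid: HyperparameterGrid | None = None,
    cv: int | None = None,
    selection: str = "auc",
    one_se: bool = False,
) -> TreeSpec:
    """Exhaustive grid search over tree hyperparameters.

    By default each configuration is scored by in-sample AUC from leaf
    positive fractions. ``cv=k`` scores it instead by out-of-fold leaf
    scores from a stratified k-fold split (seeded), which resists label
    noise: in-sample AUC always prefers trees that memorize mislabeled
    patients. ``selection="balanced"`` scores by the best swept
    (sensitivity+specificity)/2 instead of rank AUC, matching the quantity
    the cutoff sweep ultimately optimizes. ``one_se`` applies the classic
    CART one-standard-error rule: among configurations scoring within one
    binomial standard error of the best, the first in preference order
    (shallowest) wins.

    Ties are broken by configuration order (shallower depth, then
    lexicographic), so the result is deterministic for a fixed seed.
    """
    grid = grid or HyperparameterGrid()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[1] != len(FEATURES):
        raise ValueError(f"matrix must have {len(FEATURES)} feature columns")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")

    folds = None
    if cv is not None:
        skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=grid.seed)
        folds = list(skf.split(X, y))

    scored: list[tuple[float, dict]] = []
    for cfg in grid.configurations(prefer_deterministic_splits=cv is not None):
        if folds is None:
            clf = DecisionTreeClassifier(random_state=grid.seed, **cfg).fit(X, y)
            pos = list(clf.classes_).index(1)
            leaf = clf.predict_proba(X)[:, pos]
        else:
            leaf = np.empty(len(y))
            for itr, ite in folds:
                clf = DecisionTreeClassifier(random_state=grid.seed, **cfg).fit(X[itr], y[itr])
                pos = list(clf.classes_).index(1)
                leaf[ite] = clf.predict_proba(X[ite])[:, pos]
        scored.append((_selection_score(leaf, y, selection), cfg))

    best_score = max(s for s, _ in scored)
    if one_se:
        n1 = int((y == 1).sum())
        n0 = len(y) - n1
        se = 0.5 * np.sqrt(max(best_score * (1 - best_score), 1e-12) * (1 / n1 + 1 / n0))
        score, chosen = next((s, c) for s, c in scored if s >= best_score - se)
    else:
        score, chosen = next((s, c) for s, c in scored if s == best_score)

    clf = DecisionTreeClassifier(random_state=grid.seed, **chosen).fit(X, y)
    return TreeSpec(
        criterion=chosen["criterion"],
        max_depth=chosen["max_depth"],
        min_samples_split=chosen["min_samples_split"],
        min_samples_leaf=chosen["min_samples_leaf"],
        max_features=chosen["max_features"],
        seed=grid.seed,
        estimator=clf,
        train_auc=score,
    )


def select_encoding(
    matrix_numeric,
    matrix_binary,
    labels,
    grid: HyperparameterGrid | None = None,
    **search_kwargs,
) -> tuple[str, TreeSpec]:
    """Grid-search both feature encodings; keep the higher selection score.

    Ties go to the numeric encoding.
    """
    Xn = np.asarray(matrix_numeric, dtype=float)
    Xb = np.asarray(matrix_binary, dtype=float)
    y = np.asarray(labels, dtype=int)
    if Xn.shape != Xb.shape or len(Xn) != len(y):
        raise ValueError("numeric and binary matrices must align with labels")
    spec_n = grid_search_cart(Xn, y, grid, **search_kwargs)
    spec_b = grid_search_cart(Xb, y, grid, **search_kwargs)
    if spec_b.train_auc > spec_n.train_auc:
        return "binary", spec_b
    return "numeric", spec_n


@dataclass
class CutoffSweepResult:
    cutoffs: list[float] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)
    best_cutoff: float = 0.0

    def as_table(self) -> list[tuple[float, float]]:
        return list(zip(self.cutoffs, self.scores))


def sweep_cutoff(tree: TreeSpec, X, y) -> CutoffSweepResult:
    """Score cutoffs 0.1..1.0: leaves predict positive when their positive
    fraction reaches the cutoff; score = (sensitivity + specificity)/2,
    the AUC of the resulting single-point ROC. Ties take the smallest
    cutoff."""
    y = np.asarray(y, dtype=int)
    scores_leaf = tree.leaf_scores(X)
    cutoffs = [round(c / 10, 1) for c in range(1, 11)]
    scores = []
    for c in cutoffs:
        pred = scores_leaf >= c - CUTOFF_EPS
        pos, neg = y == 1, y == 0
        sens = (pred & pos).sum() / pos.sum() if pos.any() else 0.0
        spec = (~pred & neg).sum() / neg.sum() if neg.any() else 0.0
        scores.append(float((sens + spec) / 2))
    best = cutoffs[int(np.argmax(scores))]  # argmax takes the first (smallest) on ties
    return CutoffSweepResult(cutoffs=cutoffs, scores=scores, best_cutoff=best)


def tree_to_rules(tree: TreeSpec, cutoff: float) -> RuleSet:
    """Flatten a fitted tree into an ordered sequential rule set.

    Depth-first, left child first; each leaf becomes one rule whose
    conditions are the root-to-leaf comparisons in path order and whose
    label is positive iff the leaf positive-class fraction ≥ cutoff.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    t = tree.estimator.tree_
    pos = tree._positive_index()
    rules: list[SequentialRule] = []

    def leaf_positive_fraction(node: int) -> float:
        counts = t.value[node][0]
        total = counts.sum()
        # sklearn >=1.3 stores normalized fractions; older versions counts
        return float(counts[pos] / total) if total > 0 else 0.0

    def walk(node: int, path: list[RuleCondition]) -> None:
        if t.children_left[node] == -1:  # leaf
            label = POSITIVE if leaf_positive_fraction(node) >= cutoff - CUTOFF_EPS else NEGATIVE
            rules.append(SequentialRule(len(rules) + 1, list(path), label))
            return
        feature = FEATURES[t.feature[node]]
        thr = float(t.threshold[node])
        walk(t.children_left[node], path + [RuleCondition(feature, Comparator.LE, thr)])
        walk(t.children_right[node], path + [RuleCondition(feature, Comparator.GT, thr)])

    walk(0, [])
    return RuleSet(rules=rules, fallback_label=None)
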