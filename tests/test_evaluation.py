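"""Evaluation statistics: exact binomial intervals, confusion metrics,
rank AUC, per-rule audit rows and prevalence summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from aerd_phenotyper.evaluation import (
    BinomialCI,
    ConfusionCounts,
    clopper_pearson,
    confusion_metrics,
    prevalence_report,
    roc_auc,
    round_half_up,
    rule_performance,
)
from aerd_phenotyper.aggregation import PatientFeatureVector
from conftest import make_vector


def cp_bisect(successes: int, trials: int, alpha: float = 0.05) -> tuple[float, float]:
    """Independent oracle: endpoints via bisection on binomial tails."""
    def solve(tail, lo, hi):
        for _ in range(200):
            mid = (lo + hi) / 2
            if tail(mid):
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    if successes == 0:
        lower = 0.0
    else:
        lower = solve(lambda p: stats.binom.sf(successes - 1, trials, p) < alpha / 2, 0.0, 1.0)
    if successes == trials:
        upper = 1.0
    else:
        upper = solve(lambda p: stats.binom.cdf(successes, trials, p) >= alpha / 2, 0.0, 1.0)
    return lower * 100, upper * 100


class TestClopperPearson:
    @pytest.mark.parametrize(
        "s, n, lo, hi",
        [(80, 100, 70.82, 87.33), (88, 100, 79.98, 93.64), (97, 100, 91.48, 99.38)],
    )
    def test_reproduces_published_intervals(self, s, n, lo, hi):
        ci = clopper_pearson(s, n)
        assert round(ci.lower, 2) == lo
        assert round(ci.upper, 2) == hi

    def test_zero_successes_lower_bound_is_zero(self):
        assert clopper_pearson(0, 10).lower == 0.0

    def test_all_successes_upper_bound_is_hundred(self):
        assert clopper_pearson(10, 10).upper == 100.0

    @pytest.mark.parametrize("s,n", [(3, 7), (1, 50), (49, 50), (17, 123), (60, 61)])
    def test_agrees_with_tail_probability_bisection(self, s, n):
        ci = clopper_pearson(s, n)
        lo, hi = cp_bisect(s, n)
        assert ci.lower == pytest.approx(lo, abs=1e-6)
        assert ci.upper == pytest.approx(hi, abs=1e-6)

    @given(st.integers(min_value=1, max_value=200))
    @settings(max_examples=25, deadline=None)
    def test_lower_bound_monotone_in_successes(self, n):
        lowers = [clopper_pearson(s, n).lower for s in range(n + 1)]
        assert all(a <= b for a, b in zip(lowers, lowers[1:]))

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 0)
        with pytest.raises(ValueError):
            clopper_pearson(11, 10)


class TestConfusionMetrics:
    def test_balanced_test_split_row(self):
        """PPV/NPV/accuracy implied by sensitivity 80% and specificity 88%
        on a balanced 100/100 split."""
        report = confusion_metrics(ConfusionCounts(tp=80, fn=20, tn=88, fp=12))
        assert round(report.ppv.point, 2) == 86.96
        assert round(report.npv.point, 2) == 81.48
        assert round(report.accuracy.point, 2) == 84.00
        # balanced classes: accuracy = (sens + spec) / 2
        assert report.accuracy.point == pytest.approx(
            (report.sensitivity.point + report.specificity.point) / 2
        )

    def test_balanced_train_split_row(self):
        report = confusion_metrics(ConfusionCounts(tp=88, fn=12, tn=97, fp=3))
        assert round(report.ppv.point, 2) == 96.70
        assert round(report.npv.point, 2) == 88.99
        assert round(report.accuracy.point, 2) == 92.50

    def test_perfect_classifier(self):
        report = confusion_metrics(ConfusionCounts(tp=50, fn=0, tn=50, fp=0))
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            assert getattr(report, name).point == 100.0

    def test_zero_denominator_is_undefined_not_zero(self):
        report = confusion_metrics(ConfusionCounts(tp=0, fn=0, tn=10, fp=0))
        assert report.sensitivity is None
        assert report.ppv is None
        assert report.specificity.point == 100.0

    def test_display_matches_published_format(self):
        ci = clopper_pearson(80, 100)
        assert ci.display() == "80.00 (70.82-87.33)"


class TestRocAuc:
    def test_constant_scores_give_half(self):
        auc, _ = roc_auc([0.5] * 20, [0, 1] * 10, ci=False)
        assert auc == 0.5

    def test_perfect_ranking_gives_one(self):
        auc, _ = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], ci=False)
        assert auc == 1.0

    def test_agrees_with_pairwise_enumeration(self, rng):
        """Mann–Whitney AUC equals direct concordant/tied pair counting."""
        for _ in range(10):
            n = int(rng.integers(6, 25))
            y = np.r_[np.ones(3, int), np.zeros(n - 3, int)]
            s = rng.integers(0, 5, size=n).astype(float)  # heavy ties
            auc, _ = roc_auc(s, y, ci=False)
            pos, neg = s[y == 1], s[y == 0]
            pairs = [(1.0 if a > b else 0.5 if a == b else 0.0) for a in pos for b in neg]
            assert auc == pytest.approx(np.mean(pairs))

    def test_invariant_under_monotone_transform(self, rng):
        s = rng.random(40)
        y = (rng.random(40) < 0.4).astype(int)
        y[:2] = [0, 1]  # both classes present
        a1, _ = roc_auc(s, y, ci=False)
        a2, _ = roc_auc(np.exp(3 * s) + 7, y, ci=False)
        assert a1 == pytest.approx(a2)

    def test_bootstrap_ci_brackets_point_and_is_seeded(self):
        rng = np.random.default_rng(5)
        y = np.r_[np.ones(30, int), np.zeros(30, int)]
        s = np.r_[rng.normal(1, 1, 30), rng.normal(0, 1, 30)]
        auc1, ci1 = roc_auc(s, y, seed=9, n_boot=300)
        auc2, ci2 = roc_auc(s, y, seed=9, n_boot=300)
        assert ci1 == ci2
        assert ci1[0] <= auc1 <= ci1[1]

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestRulePerformance:
    @pytest.mark.parametrize("correct, cases, conf", [(40, 43, 93), (12, 30, 40), (3, 4, 75)])
    def test_confidence_formula(self, correct, cases, conf):
        assert int(round_half_up(100 * correct / cases)) == conf

    def test_zero_cases_confidence_zero(self, ruleset):
        rows = rule_performance(ruleset, [], [])
        assert all(r.cases == 0 and r.confidence == 0 for r in rows)

    def test_counts_and_confidence_on_constructed_cohort(self, ruleset):
        # three patients matching rule 9 (two gold-positive, one gold-negative)
        vecs = [
            PatientFeatureVector("a", make_vector(AERD=4, NSAID_ALLERGY=2)),
            PatientFeatureVector("b", make_vector(AERD=5, NSAID_ALLERGY=3)),
            PatientFeatureVector("c", make_vector(AERD=6, NSAID_ALLERGY=2)),
        ]
        rows = rule_performance(ruleset, vecs, [1, 1, 0])
        row9 = next(r for r in rows if r.rule_id == 9)
        assert (row9.cases, row9.correct, row9.error) == (3, 2, 1)
        assert row9.confidence == 67  # round_half_up(200/3)

    def test_expected_assignment_separates_cases_from_matches(self, ruleset):
        """A patient expected at rule 6 but diverted to rule 9 counts as a
        rule-6 case that rule 6 neither got right nor wrong."""
        v = PatientFeatureVector("a", make_vector(AERD=4, NSAID_ALLERGY=3))
        rows = rule_performance(ruleset, [v], [1], expected_rule_assignment={"a": 6})
        row6 = next(r for r in rows if r.rule_id == 6)
        assert (row6.cases, row6.correct, row6.error, row6.confidence) == (1, 0, 0, 0)


class TestPrevalence:
    def test_published_style_rounding(self):
        X = np.zeros((200, 7), dtype=int)
        X[:103, 0] = 1  # feature present in 103 of 200 patients
        rep = prevalence_report(X)
        assert rep.loc[0, "n"] == 103 and rep.loc[0, "percent"] == 52

    def test_absent_feature(self):
        rep = prevalence_report(np.zeros((10, 7), dtype=int))
        assert (rep["n"] == 0).all() and (rep["percent"] == 0).all()

    def test_counts_are_presence_not_frequency(self):
        X = np.zeros((4, 7), dtype=int)
        X[0, 2] = 9
        rep = prevalence_report(X)
        assert rep.loc[2, "n"] == 1 and rep.loc[2, "percent"] == 25
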