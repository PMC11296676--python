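# Methods

This note records the model, the conventions the implementation fixes
where the underlying procedure is underdetermined, and what the synthetic
data does and does not establish.

## Phenotyping model

The classifier is a function of seven per-patient mention counts. A
*mention* is one non-overlapping lexicon-pattern occurrence inside a
whitelisted note section; the count is the number of such mentions in the
closed window `[anchor − w, anchor]`, with `w = 5` years by default and
the anchor at the patient's latest document date (a proxy for the last
clinic visit — the only date signal in the data model). Window arithmetic
uses 365.25-day years and is closed on both ends: a mention dated exactly
five years before the anchor counts. Counting is per mention, not per
document ("the number of times the feature appeared"); a per-document
variant (`AggregationConfig(unit="document")`, distinct dates as the
document proxy) exists as an explicitly unvalidated convention.

Decision thresholds in the rule set are half-integers (3.5, 2.5, 6.5, 9.0,
0.5, 1.5) because CART places splits at midpoints between observed integer
counts; conditions are evaluated with exact `≤`/`>` comparisons, and
integer counts make ties impossible.

### Lexicons

The original feature dictionaries are not public. The shipped lexicon is
therefore *documented replaceable data* (YAML-serializable), chosen to
cover canonical phrases, abbreviations and a few typo variants per
feature. Matching is case-insensitive on word boundaries with flexible
internal whitespace. Overlap resolution is global leftmost-longest across
**all** features, not only within a feature: an allergy phrase embedded in
an explicit tolerance statement ("no NSAID allergy") must yield only the
longer, negated-meaning mention, otherwise every documented-tolerance
sentence would also count as an allergy mention. The
documented-no-NSAID-allergy feature is pattern-based (explicit tolerance
phrases), not NegEx-style negation scoping: the feature represents a
provider's recorded statement, not an inference.

The LAB feature is a sentence pattern capturing a numeric urinary
leukotriene E4 value; a mention is emitted only for values strictly
greater than 104 pg/mg creatinine. Unparseable values skip the sentence
with a warning.

### Section model

A section header is a line whose stripped text equals a vocabulary name
plus `:`(case-insensitive); compound names ("Impression/Report/Plan")
match literally. Segmentation partitions the document: every character
belongs to exactly one span, text before the first header is UNLABELED.
Offsets are 0-based half-open.

## Synthetic corpus

The generator emulates sectioned specialist-clinic notes with planted,
ground-truthed mentions:

* **Count model.** Per class (AERD case vs. control) and feature, target
  counts follow truncated geometric distributions on 0..12. Parameters
  were fixed once so class-conditional presence rates resemble a
  specialist-clinic case/control cohort (cases: prior-AERD ≈ 88%,
  asthma ≈ 96%, NSAID-reaction ≈ 85%, chronic sinusitis ≈ 92%; controls:
  sinus/asthma-heavy but prior-AERD ≈ 15%, NSAID-reaction ≈ 20%). They are
  plausible skewed count data, not a reconstruction of any real cohort.
* **Label consistency.** Draws are rejection-matched to the published
  nine-rule classifier, so at zero label noise every profile's gold label
  equals the rule set's classification of its target counts — making
  rule-set recovery experiments well-posed.
* **Label noise.** With probability `label_noise_rate` a patient's counts
  are drawn from the *opposite* class's distributions while the gold label
  keeps the intended class. This models patients whose documentation does
  not reflect their disease. Such patients are unidentifiable from their
  notes by construction; performance measured against gold labels on
  noisy data is therefore ceiling-limited at 1 − noise.
* **Decoys.** Decoy mentions are planted (a) in non-whitelisted sections
  such as Family History and (b) in whitelisted sections of documents
  dated strictly outside the 5-year window, so both exclusion paths of the
  extraction stage are exercised. Occasional non-elevated LAB sentences
  (≤ 104 pg/mg) exercise the threshold rule.
* **Filler.** All other prose comes from a fixed pattern-free sentence
  list, so extract → aggregate reproduces the planted counts exactly —
  a hard, tested invariant rather than a probabilistic one.
* **Dates.** ISO 8601, one date per document; the last-visit document
  anchors the window.

What the generator does **not** emulate: realistic clinical prose,
misspellings beyond the listed variants, negation/uncertainty phenomena,
multi-encounter structure, structured lab records, or the document-count
and mention-count distributions of any real EHR (which are unpublished).
Passing round-trip tests therefore validates the pipeline's mechanics —
sectioning, matching, windowing, counting — not extraction recall on real
notes, where unseen phrasings dominate the error budget.

## Training

`grid_search_cart` enumerates the full 7000-configuration grid with a
fixed random state (default 20) and scores each configuration from its
leaf positive-class fractions. Two scoring modes exist:

* `selection="auc"` (default): Mann–Whitney rank AUC, threshold-free.
* `selection="balanced"`: the best swept (sensitivity + specificity)/2
  over cutoffs 0.1–1.0 — the "AUC of the single-point ROC" that a
  thresholded tree actually realizes, and the quantity the final cutoff
  sweep optimizes.

Scores are computed in-sample by default (the derivation procedure as
described, with no cross-validation) or out-of-fold with `cv=k`
(stratified, seeded). In-sample selection should be treated as unsafe
under label noise: a tree that memorizes mislabeled patients always
attains in-sample AUC 1.0, so the grid maximum is systematically an
overfit tree; its isolation leaves cover large empty regions of count
space and misclassify clean patients far beyond the noise floor. With
noisy labels use `cv=5, selection="balanced", one_se=True`.

`one_se=True` applies the classic CART one-standard-error rule: among
configurations scoring within one binomial standard error of the best,
the first in preference order wins. Preference order is shallower
max_depth, then lexicographic (criterion, min_samples_split,
min_samples_leaf) — and, in cross-validated mode, **descending**
max_features: a configuration with sub-sampled split features is refit on
the full training set as a *fresh random draw* that its fold scores do not
describe, so among statistically indistinguishable configurations the
deterministic exhaustive split search (max_features = 7) is preferred.

Encoding selection fits both the count and the binarized matrix and keeps
the higher score; ties go to the count encoding. The cutoff sweep scores
c ∈ {0.1, …, 1.0} by in-sample (sens + spec)/2 with ties to the smallest
cutoff. Leaf-fraction-vs-cutoff comparisons use a 1e-9 slack because both
sides are short decimals whose binary representations can straddle
equality.

`tree_to_rules` emits one rule per leaf in depth-first left-to-right
order; left child ⇒ `≤ threshold`, right ⇒ `>`. Rule labels are fixed at
conversion time (leaf fraction ≥ cutoff); the cutoff is never re-applied
at classification time.

## Rules engine

Classification is strict first-match over the ordered rules; it is a pure
function of (vector, rule set). Because any tree-derived rule set's
conjunctions are the leaves of a binary partition, exactly one rule
matches any complete vector — `coverage_check` verifies this by grid
enumeration (exhaustive when the grid fits, else a seeded uniform
subsample). The published rule table lists a tenth "Others" row even
though its nine explicit rules already partition the space; here "Others"
exists only as an optional fallback label for rule sets that do not cover
the space, and is unreachable for the default classifier.

## Evaluation

* **Proportion CIs.** Clopper–Pearson exact two-sided intervals from beta
  quantiles, reported in percent; endpoints pinned to 0/100 at the
  boundaries. The method reproduces every published interval it is tested
  against, which is why it is the package's (otherwise unattributed)
  convention.
* **Zero denominators** make a metric undefined (reported as None), never 0.
* **AUC** is the midrank Mann–Whitney statistic; its CI is a seeded
  stratified bootstrap (default 2000 resamples, percentile endpoints) —
  a labeled convention, as no exact small-sample interval is standard.
* **Rule audit.** Per rule: cases (patients expected at the rule, or
  matched by it when no expectation table is supplied), correct/error
  (label agreement among cases where the rule actually fired), and
  confidence = 100·correct/cases rounded half-up to an integer (0 when no
  cases).
* **Display rounding** is half-up to 2 decimals for metrics, integers for
  prevalence percentages.

## Problem sizes in the test suite

The acceptance-style tests use sizes chosen to make their properties
sharp while keeping the suite quick: rule/tree equivalence and recovery
agreement are evaluated on 10⁵ vectors subsampled uniformly from the
13⁷-point count grid; rule-set recovery trains on 2000 uniform labelled
count vectors (uniform counts put mass on both sides of every decision
threshold, so thresholds are identifiable); the noise-robustness check
trains on a 200/200 cohort with 10% label noise and evaluates on an
independent 1000/1000 cleanly-documented cohort; interval coverage uses
10⁴ replicates at n = 100. End-to-end pipeline tests run a reduced 12/12
per-split cohort; the full 100/100 protocol is exercised by the CLI
example.

## Known limitations

* The lexicon is a demonstration dictionary; real-world recall requires
  site-specific curation (the dominant error source in deployment).
* Sections are recognized only via `Header:` lines; notes without
  explicit headers fall into UNLABELED and are excluded by the whitelist.
* "Last clinic visit" is proxied by the latest document date.
* In-sample model selection is kept as the faithful default derivation
  mode despite its noise sensitivity (see Training); the cross-validated
  mode is the recommended practice.
* Whether a patient can simultaneously carry allergy and
  documented-tolerance mentions is not adjudicated; both features are
  extracted independently.
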