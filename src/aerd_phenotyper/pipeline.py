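"""End-to-end driver: simulate → extract → aggregate → train → classify →
evaluate, with stage file formats, validation and a reproducibility
manifest.

All randomness flows from one global seed through fixed per-stage
derivations, so a rerun with the same configuration is byte-identical.
The default protocol mirrors a balanced case/control design: a 200/200
cohort split into a 100/100 training set and a 100/100 test set.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aggregation import (
    AggregationConfig,
    binarize,
    build_matrix,
    count_features,
    read_matrix,
    write_matrix,
)
from .documents import read_notes, write_notes
from .evaluation import (
    ConfusionCounts,
    confusion_metrics,
    prevalence_report,
    roc_auc,
    rule_performance,
    rule_performance_frame,
)
from .features import FEATURES
from .lexicon import FeatureLexicon, default_lexicon
from .rules_engine import POSITIVE, RuleSet, classify_matrix
from .synthetic_corpus import CorpusConfig, generate_cohort, write_truth
from .text_extraction import extract_corpus, read_mentions, write_mentions
from .training import HyperparameterGrid, select_encoding, sweep_cutoff, tree_to_rules

logger = logging.getLogger(__name__)


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    seed: int = 20
    n_train_positive: int = 100
    n_train_negative: int = 100
    n_test_positive: int = 100
    n_test_negative: int = 100
    label_noise_rate: float = 0.10
    typo_rate: float = 0.10
    window_years: float = 5.0

    def __post_init__(self) -> None:
        for name in ("n_train_positive", "n_train_negative", "n_test_positive", "n_test_negative"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _stratified_split(labels: pd.Series, sizes: tuple[int, int, int, int], seed: int):
    """Return (train_ids, test_ids) with the requested per-class sizes."""
    ntp, ntn, nsp, nsn = sizes
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for cls, n_train, n_test in ((1, ntp, nsp), (0, ntn, nsn)):
        ids = sorted(labels.index[labels == cls])
        if len(ids) < n_train + n_test:
            raise ValueError(
                f"class {cls} has {len(ids)} patients, need {n_train + n_test}"
            )
        perm = rng.permutation(len(ids))
        train_ids += [ids[i] for i in perm[:n_train]]
        test_ids += [ids[i] for i in perm[n_train:n_train + n_test]]
    return sorted(train_ids), sorted(test_ids)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage, write all artifacts under ``outdir``, and
    return the run manifest (also written as ``manifest.json``)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    lexicon = default_lexicon()
    manifest: dict = {
        "package": "aerd-phenotyper",
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
    }

    # 1. simulate
    corpus_cfg = CorpusConfig(
        n_positive=config.n_train_positive + config.n_test_positive,
        n_negative=config.n_train_negative + config.n_test_negative,
        label_noise_rate=config.label_noise_rate,
        typo_rate=config.typo_rate,
        seed=derive_seed(config.seed, "simulate"),
    )
    documents, profiles = generate_cohort(corpus_cfg, lexicon)
    write_notes(documents, out / "notes.jsonl")
    write_truth(profiles, out / "truth.tsv")
    logger.info("simulate: %d documents, %d patients", len(documents), len(profiles))
    manifest["stages"]["simulate"] = {
        "notes": "notes.jsonl", "truth": "truth.tsv",
        "n_documents": len(documents), "n_patients": len(profiles),
    }

    # 2. extract
    mentions = extract_corpus(documents, lexicon)
    write_mentions(mentions, out / "mentions.tsv")
    logger.info("extract: %d valid mentions", len(mentions))
    manifest["stages"]["extract"] = {"mentions": "mentions.tsv", "n_mentions": len(mentions)}

    # 3. aggregate
    anchors = {}
    patient_ids = []
    for doc in documents:
        if doc.patient_id not in anchors:
            patient_ids.append(doc.patient_id)
            anchors[doc.patient_id] = doc.doc_date
        else:
            anchors[doc.patient_id] = max(anchors[doc.patient_id], doc.doc_date)
    vectors = count_features(
        mentions, AggregationConfig(window_years=config.window_years),
        patient_ids=patient_ids, anchors=anchors,
    )
    gold = {p.patient_id: p.aerd_label for p in profiles}
    for v in vectors:
        v.label = gold[v.patient_id]
    Xn, y = build_matrix(vectors, "numeric")
    Xb, _ = build_matrix(vectors, "binary")
    write_matrix(Xn, y, out / "matrix_numeric.tsv")
    write_matrix(Xb, y, out / "matrix_binary.tsv")
    manifest["stages"]["aggregate"] = {
        "matrix_numeric": "matrix_numeric.tsv", "matrix_binary": "matrix_binary.tsv",
        "n_patients": len(vectors),
    }

    # 4. split
    train_ids, test_ids = _stratified_split(
        y,
        (config.n_train_positive, config.n_train_negative,
         config.n_test_positive, config.n_test_negative),
        derive_seed(config.seed, "split"),
    )
    manifest["stages"]["split"] = {"n_train": len(train_ids), "n_test": len(test_ids)}

    # 5. train
    grid = HyperparameterGrid(seed=config.seed)
    encoding, tree = select_encoding(
        Xn.loc[train_ids], Xb.loc[train_ids], y.loc[train_ids], grid
    )
    X_train = (Xn if encoding == "numeric" else Xb).loc[train_ids]
    sweep = sweep_cutoff(tree, X_train, y.loc[train_ids])
    ruleset = tree_to_rules(tree, sweep.best_cutoff)
    ruleset.to_yaml(out / "rules.yaml")
    pd.DataFrame({"cutoff": sweep.cutoffs, "score": sweep.scores}).to_csv(
        out / "cutoff_sweep.tsv", sep="\t", index=False
    )
    logger.info(
        "train: encoding=%s params=%s auc=%.3f cutoff=%.1f",
        encoding, tree.params, tree.train_auc, sweep.best_cutoff,
    )
    manifest["stages"]["train"] = {
        "encoding": encoding, "params": tree.params,
        "train_auc": tree.train_auc, "best_cutoff": sweep.best_cutoff,
        "rules": "rules.yaml", "n_rules": len(ruleset.rules),
    }

    # 6. classify the test set with the derived sequential rules
    X_test = (Xn if encoding == "numeric" else Xb).loc[test_ids]
    pred, rule_ids = classify_matrix(X_test.to_numpy(), ruleset)
    preds = pd.DataFrame(
        {"patient_id": test_ids, "predicted_label": pred, "matched_rule_id": rule_ids}
    )
    preds.to_csv(out / "predictions.tsv", sep="\t", index=False)
    manifest["stages"]["classify"] = {"predictions": "predictions.tsv", "n_test": len(preds)}

    # 7. evaluate
    y_test = y.loc[test_ids].to_numpy(dtype=int)
    report = confusion_metrics(ConfusionCounts.from_predictions(y_test, pred))
    auc, auc_ci = roc_auc(
        tree.leaf_scores(X_test), y_test, seed=derive_seed(config.seed, "auc_bootstrap")
    )
    report.auc, report.auc_ci = auc, auc_ci
    from .aggregation import vectors_from_matrix  # local import avoids cycle at module load

    test_vectors = vectors_from_matrix(X_test, y.loc[test_ids])
    audit = rule_performance_frame(rule_performance(ruleset, test_vectors, list(y_test)))
    audit.to_csv(out / "rule_audit.tsv", sep="\t", index=False)
    prevalence_report(Xb.loc[train_ids]).to_csv(out / "prevalence_train.tsv", sep="\t", index=False)
    prevalence_report(Xb.loc[test_ids]).to_csv(out / "prevalence_test.tsv", sep="\t", index=False)
    with open(out / "metrics.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    manifest["stages"]["evaluate"] = {
        "metrics": "metrics.json", "rule_audit": "rule_audit.tsv",
        "prevalence_train": "prevalence_train.tsv", "prevalence_test": "prevalence_test.tsv",
        "test_metrics": report.to_dict(),
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# -- format validation ----------------------------------------------------

SCHEMAS = ("notes", "truth", "mentions", "matrix", "rules")


def validate_formats(path, schema: str) -> list[tuple[int, str]]:
    """Line-level schema validation; returns (line_number, message) pairs."""
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {SCHEMAS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    violations: list[tuple[int, str]] = []

    if schema == "notes":
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as e:
                    violations.append((i, f"invalid JSON: {e}"))
                    continue
                for key in ("patient_id", "doc_date", "sections"):
                    if key not in rec:
                        violations.append((i, f"missing field {key!r}"))
                if "doc_date" in rec:
                    try:
                        pd.Timestamp(rec["doc_date"])
                    except ValueError:
                        violations.append((i, f"unparseable doc_date {rec['doc_date']!r}"))
                for s in rec.get("sections", []):
                    if not isinstance(s, dict) or "header" not in s or "text" not in s:
                        violations.append((i, "section must have 'header' and 'text'"))
        return violations

    if schema == "rules":
        try:
            RuleSet.from_yaml(path)
        except Exception as e:  # surfaced as a single top-level violation
            violations.append((0, f"invalid rule set: {e}"))
        return violations

    expected_cols = {
        "truth": ["patient_id", "label", *FEATURES],
        "mentions": ["patient_id", "feature", "section", "date", "start", "end", "pattern"],
        "matrix": ["patient_id", "label", *FEATURES],
    }[schema]
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != expected_cols:
            violations.append((1, f"header {header} != expected {expected_cols}"))
            return violations
        for i, line in enumerate(fh, 2):
            if not line.strip():
                continue
            fields_ = line.rstrip("\n").split("\t")
            if len(fields_) != len(expected_cols):
                violations.append((i, f"expected {len(expected_cols)} fields, got {len(fields_)}"))
                continue
            row = dict(zip(expected_cols, fields_))
            if schema == "mentions":
                numeric = ("start", "end")
                try:
                    pd.Timestamp(row["date"])
                except ValueError:
                    violations.append((i, f"unparseable date {row['date']!r}"))
            else:
                numeric = ("label", *FEATURES)
            for col in numeric:
                try:
                    float(row[col])
                except ValueError:
                    violations.append((i, f"non-numeric {col}: {row[col]!r}"))
    return violations
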