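"""Per-patient feature aggregation over a lookback window.

Valid mentions are counted per patient and feature inside a closed window
of ``window_years`` (365.25-day years, default 5) ending at the patient's
anchor date — by default the latest document date seen for that patient,
standing in for the last clinic visit. The counts form the numeric feature
representation; a binary view (presence/absence) is derived from it.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import FEATURES
from .text_extraction import FeatureMention

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25


@dataclass
class AggregationConfig:
    window_years: float = 5.0
    #: "latest_doc" anchors each patient's window at their newest document
    anchor: str = "latest_doc"
    #: "mention" counts every occurrence; "document" counts documents
    #: containing at least one occurrence
    unit: str = "mention"

    def __post_init__(self) -> None:
        if self.window_years <= 0:
            raise ValueError("window_years must be positive")
        if self.unit not in ("mention", "document"):
            raise ValueError("unit must be 'mention' or 'document'")


@dataclass
class PatientFeatureVector:
    patient_id: str
    counts: dict[str, int] = field(default_factory=dict)
    label: int | None = None

    def __post_init__(self) -> None:
        full = {f: int(self.counts.get(f, 0)) for f in FEATURES}
        if any(v < 0 for v in full.values()):
            raise ValueError("counts must be non-negative")
        extra = set(self.counts) - set(FEATURES)
        if extra:
            raise ValueError(f"unknown feature ids in counts: {sorted(extra)}")
        self.counts = full

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[f] for f in FEATURES], dtype=float)


def count_features(
    mentions: list[FeatureMention],
    config: AggregationConfig | None = None,
    patient_ids: list[str] | None = None,
    anchors: dict[str, dt.date] | None = None,
) -> list[PatientFeatureVector]:
    """Count in-window mentions per patient and feature.

    ``patient_ids`` forces all-zero vectors for patients with no (in-window)
    mentions; ``anchors`` overrides the per-patient window anchor (otherwise
    the latest mention date is used). The window is closed on both ends:
    a mention dated exactly ``anchor - window`` is included.
    """
    config = config or AggregationConfig()
    window_days = config.window_years * DAYS_PER_YEAR

    by_patient: dict[str, list[FeatureMention]] = {}
    for m in mentions:
        if m.doc_date is None:
            logger.warning("mention without a date excluded: %s/%s", m.patient_id, m.feature)
            continue
        by_patient.setdefault(m.patient_id, []).append(m)

    ids = list(patient_ids) if patient_ids is not None else sorted(by_patient)
    for pid in by_patient:
        if pid not in ids:
            ids.append(pid)

    vectors = []
    for pid in ids:
        ms = by_patient.get(pid, [])
        counts: dict[str, int] = {f: 0 for f in FEATURES}
        if ms:
            if anchors is not None and pid in anchors:
                anchor = anchors[pid]
            else:
                anchor = max(m.doc_date for m in ms)
            in_window = [m for m in ms if 0 <= (anchor - m.doc_date).days <= window_days]
            if config.unit == "mention":
                for m in in_window:
                    counts[m.feature] += 1
            else:  # document-level: distinct documents proxied by distinct dates
                seen: set[tuple[str, dt.date]] = set()
                for m in in_window:
                    key = (m.feature, m.doc_date)
                    if key not in seen:
                        seen.add(key)
                        counts[m.feature] += 1
        vectors.append(PatientFeatureVector(pid, counts))
    return vectors


def binarize(vector: PatientFeatureVector) -> PatientFeatureVector:
    """Presence/absence view: 1 iff the count is positive. Idempotent."""
    return replace(vector, counts={f: int(vector.counts[f] > 0) for f in FEATURES})


def build_matrix(
    vectors: list[PatientFeatureVector], encoding: str = "numeric"
) -> tuple[pd.DataFrame, pd.Series]:
    """Stack vectors into an (n_patients × 7) frame plus aligned labels.

    Columns follow the canonical feature order; the index is patient_id.
    ``encoding="binary"`` is exactly ``binarize`` applied first.
    """
    if encoding not in ("numeric", "binary"):
        raise ValueError("encoding must be 'numeric' or 'binary'")
    ids = [v.patient_id for v in vectors]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate patient ids: {dupes}")
    vs = [binarize(v) if encoding == "binary" else v for v in vectors]
    X = pd.DataFrame(
        [[v.counts[f] for f in FEATURES] for v in vs], index=pd.Index(ids, name="patient_id"),
        columns=list(FEATURES), dtype=int,
    )
    y = pd.Series([v.label for v in vectors], index=X.index, name="label")
    return X, y


# -- matrix table I/O -----------------------------------------------------

def write_matrix(X: pd.DataFrame, y: pd.Series, path) -> None:
    out = X.copy()
    out.insert(0, "label", y)
    out.to_csv(path, sep="\t")


def read_matrix(path) -> tuple[pd.DataFrame, pd.Series]:
    df = pd.read_csv(path, sep="\t", index_col="patient_id")
    y = df["label"] if "label" in df else pd.Series(index=df.index, dtype=float, name="label")
    X = df[[c for c in FEATURES]]
    return X, y


def vectors_from_matrix(X: pd.DataFrame, y: pd.Series | None = None) -> list[PatientFeatureVector]:
    labels = y if y is not None else pd.Series(index=X.index, dtype=object)
    out = []
    for pid, row in X.iterrows():
        lab = labels.get(pid)
        lab = None if lab is None or (isinstance(lab, float) and np.isnan(lab)) else int(lab)
        out.append(PatientFeatureVector(str(pid), {f: int(row[f]) for f in FEATURES}, lab))
    return out
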