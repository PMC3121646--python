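"""Core containers shared across the package.

The unit of work is a labeled table of instances (e.g. genes) with numeric
features (e.g. expression across cell lines) and one categorical class label
per instance.  Classifiers communicate exclusively through row-stochastic
posterior matrices, and every downstream evaluation step consumes flat
tables of per-instance prediction records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

ROW_SUM_TOL = 1e-9


class AlignmentError(ValueError):
    """Raised when two objects that must share instances/classes do not."""


@dataclass
class LabeledDataset:
    """Feature matrix plus class labels and an ordered class vocabulary."""

    instance_ids: list[str]
    features: np.ndarray  # (n, d)
    labels: np.ndarray  # (n,) of class names
    class_vocab: list[str]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        n = self.features.shape[0]
        if not (len(self.instance_ids) == len(self.labels) == n):
            raise ValueError(
                f"inconsistent sizes: {len(self.instance_ids)} ids, "
                f"{len(self.labels)} labels, {n} feature rows"
            )
        vocab = set(self.class_vocab)
        if len(vocab) != len(self.class_vocab):
            raise ValueError("class_vocab contains duplicates")
        unknown = set(self.labels) - vocab
        if unknown:
            raise ValueError(f"labels outside class_vocab: {sorted(unknown)}")
        present = set(self.labels)
        empty = [c for c in self.class_vocab if c not in present]
        if empty:
            raise ValueError(f"classes with no instances: {empty}")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_vocab)

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in self.class_vocab}

    def subset(self, idx: Sequence[int]) -> "LabeledDataset":
        """Row subset; keeps the full class vocabulary only if every class
        survives, otherwise shrinks the vocabulary to the classes present."""
        idx = np.asarray(idx, dtype=int)
        labels = self.labels[idx]
        present = set(labels)
        vocab = [c for c in self.class_vocab if c in present]
        return LabeledDataset(
            instance_ids=[self.instance_ids[i] for i in idx],
            features=self.features[idx],
            labels=labels,
            class_vocab=vocab,
        )

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        feat = pd.DataFrame(
            self.features,
            index=pd.Index(self.instance_ids, name="instance_id"),
            columns=[f"f{j}" for j in range(self.d)],
        )
        lab = pd.DataFrame(
            {"class": self.labels},
            index=pd.Index(self.instance_ids, name="instance_id"),
        )
        return feat, lab


@dataclass
class PosteriorMatrix:
    """Class-membership probabilities from one classifier, rows sum to 1."""

    model_id: str
    instance_ids: list[str]
    probs: np.ndarray  # (n, C)
    class_vocab: list[str]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2:
            raise ValueError("probs must be 2-D")
        if self.probs.shape != (len(self.instance_ids), len(self.class_vocab)):
            raise ValueError(
                f"probs shape {self.probs.shape} inconsistent with "
                f"{len(self.instance_ids)} instances x {len(self.class_vocab)} classes"
            )
        if self.probs.size:
            if np.min(self.probs) < -ROW_SUM_TOL or np.max(self.probs) > 1 + ROW_SUM_TOL:
                raise ValueError("probabilities outside [0, 1]")
            sums = self.probs.sum(axis=1)
            if np.max(np.abs(sums - 1.0)) > ROW_SUM_TOL:
                raise ValueError("rows of a posterior matrix must sum to 1")

    @property
    def n(self) -> int:
        return self.probs.shape[0]


@dataclass
class PredictionRecord:
    """One scored prediction: the atomic row of every evaluation table."""

    instance_id: str
    model_id: str
    predicted_class: str
    true_class: Optional[str] = None
    maxp: float = np.nan
    pin: float = np.nan
    pic: float = np.nan

    @property
    def correct(self) -> bool:
        if self.true_class is None:
            raise ValueError("correctness undefined without a true class")
        return self.predicted_class == self.true_class

    def with_pin(self, pin: float) -> "PredictionRecord":
        return replace(self, pin=float(pin))

    def with_pic(self, pic: float) -> "PredictionRecord":
        return replace(self, pic=float(pic))


RECORD_COLUMNS = [
    "instance_id",
    "model_id",
    "predicted_class",
    "true_class",
    "maxp",
    "pin",
    "pic",
]


def records_to_frame(records: Sequence[PredictionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "instance_id": r.instance_id,
                "model_id": r.model_id,
                "predicted_class": r.predicted_class,
                "true_class": r.true_class,
                "maxp": r.maxp,
                "pin": r.pin,
                "pic": r.pic,
            }
            for r in records
        ],
        columns=RECORD_COLUMNS,
    )


def frame_to_records(df: pd.DataFrame) -> list[PredictionRecord]:
    recs = []
    for row in df.itertuples(index=False):
        true_class = row.true_class
        if true_class is not None and (isinstance(true_class, float) and np.isnan(true_class)):
            true_class = None
        recs.append(
            PredictionRecord(
                instance_id=str(row.instance_id),
                model_id=str(row.model_id),
                predicted_class=str(row.predicted_class),
                true_class=None if true_class is None else str(true_class),
                maxp=float(row.maxp),
                pin=float(row.pin),
                pic=float(row.pic),
            )
        )
    return recs


def scores_of(records: Sequence[PredictionRecord], score_name: str) -> np.ndarray:
    """Extract a named confidence score (maxp / pin / pic) as an array."""
    key = score_name.lower()
    aliases = {"maxp": "maxp", "pin": "pin", "maxpin": "pin", "pic": "pic"}
    if key not in aliases:
        raise ValueError(f"unknown score name: {score_name!r}")
    attr = aliases[key]
    vals = np.array([getattr(r, attr) for r in records], dtype=float)
    if np.isnan(vals).any():
        raise ValueError(f"score {score_name!r} is unset on some records")
    return vals


def correctness_of(records: Sequence[PredictionRecord]) -> np.ndarray:
    return np.array([r.correct for r in records], dtype=bool)
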