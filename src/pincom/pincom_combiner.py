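"""Combining heterogeneous classifiers on the common PIN scale.

The PIN Combined Classifier (PINCom) classifies each instance into the
predicted class of whichever base model has the highest PIN there; its own
confidence score is that maximum, MaxPIN.  Three standard combiners ship as
comparators: plurality voting with random tie-breaks, and two stacked
generalisers trained on cross-validated level-0 outputs (multi-response
linear regression, and a random forest over probabilities plus one-hot
predicted classes).  A leave-one-model-out ablation quantifies each model's
contribution to the combined recall at fixed precision levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .datatypes import AlignmentError, PredictionRecord
from .pr_curves import UnreachablePrecisionError, rp_curve, threshold_for_precision

PINCOM_ID = "PINCom"


@dataclass
class CombinedPrediction:
    """PINCom's decision for one instance."""

    instance_id: str
    per_model: dict[str, tuple[str, float]]  # model_id -> (predicted_class, pin)
    winning_model_id: str
    predicted_class: str
    max_pin: float
    true_class: str | None = None

    def to_record(self) -> PredictionRecord:
        return PredictionRecord(
            instance_id=self.instance_id,
            model_id=PINCOM_ID,
            predicted_class=self.predicted_class,
            true_class=self.true_class,
            maxp=self.max_pin,  # MaxPIN plays the role of MaxP for PINCom
            pin=self.max_pin,
        )


def _check_alignment(per_model_records: Sequence[Sequence[PredictionRecord]]) -> None:
    first = per_model_records[0]
    ids = [r.instance_id for r in first]
    for recs in per_model_records[1:]:
        if [r.instance_id for r in recs] != ids:
            raise AlignmentError("models cover different instances or orders")
        for a, b in zip(first, recs):
            if a.true_class != b.true_class:
                raise AlignmentError("models disagree on true classes")


def combine_pin(
    per_model_records: Sequence[Sequence[PredictionRecord]], seed: int = 0
) -> list[CombinedPrediction]:
    """Classify each instance by the model with the highest PIN.

    Ties at the maximum PIN are resolved by a uniform random choice among
    the tied models, from a dedicated RNG stream seeded by ``seed``.
    """
    if len(per_model_records) < 2:
        raise ValueError("combining needs at least 2 models")
    _check_alignment(per_model_records)
    rng = np.random.default_rng(seed)
    out = []
    n = len(per_model_records[0])
    for i in range(n):
        row = [recs[i] for recs in per_model_records]
        pins = np.array([r.pin for r in row], dtype=float)
        if np.isnan(pins).any():
            raise ValueError("all records must carry PIN before combining")
        top = float(pins.max())
        tied = np.flatnonzero(pins == top)
        winner = row[int(rng.choice(tied))] if tied.size > 1 else row[int(tied[0])]
        out.append(
            CombinedPrediction(
                instance_id=row[0].instance_id,
                per_model={r.model_id: (r.predicted_class, float(r.pin)) for r in row},
                winning_model_id=winner.model_id,
                predicted_class=winner.predicted_class,
                max_pin=top,
                true_class=row[0].true_class,
            )
        )
    return out


def combined_to_records(combined: Sequence[CombinedPrediction]) -> list[PredictionRecord]:
    return [c.to_record() for c in combined]


def combined_to_frame(combined: Sequence[CombinedPrediction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "instance_id": c.instance_id,
                "model_id": PINCOM_ID,
                "predicted_class": c.predicted_class,
                "true_class": c.true_class,
                "maxp": c.max_pin,
                "pin": c.max_pin,
                "pic": np.nan,
                "winning_model_id": c.winning_model_id,
                "max_pin": c.max_pin,
            }
            for c in combined
        ]
    )


def vote_combine(
    per_model_records: Sequence[Sequence[PredictionRecord]], seed: int = 0
) -> list[PredictionRecord]:
    """Plurality vote over the models' predicted classes, random tie-break."""
    if len(per_model_records) == 1:
        return list(per_model_records[0])
    _check_alignment(per_model_records)
    rng = np.random.default_rng(seed)
    out = []
    n = len(per_model_records[0])
    for i in range(n):
        row = [recs[i] for recs in per_model_records]
        votes: dict[str, int] = {}
        for r in row:
            votes[r.predicted_class] = votes.get(r.predicted_class, 0) + 1
        top = max(votes.values())
        tied = sorted(c for c, v in votes.items() if v == top)
        cls = tied[int(rng.integers(len(tied)))] if len(tied) > 1 else tied[0]
        out.append(
            PredictionRecord(
                instance_id=row[0].instance_id,
                model_id="Vote",
                predicted_class=cls,
                true_class=row[0].true_class,
                maxp=top / len(row),
            )
        )
    return out


def _stack_blocks(prob_blocks: Sequence[np.ndarray]) -> np.ndarray:
    shapes = {b.shape for b in map(np.asarray, prob_blocks)}
    if len({s[0] for s in shapes}) != 1:
        raise AlignmentError("probability blocks have mismatched row counts")
    return np.hstack([np.asarray(b, dtype=float) for b in prob_blocks])


@dataclass
class Stack1Model:
    """Multi-response linear regression over level-0 class probabilities."""

    classes: list[str]
    coef: np.ndarray  # (1 + L*C, C): intercept + weights per class response


def stack1_fit(
    prob_blocks: Sequence[np.ndarray], true_labels: Sequence[str]
) -> Stack1Model:
    """Least-squares regression of each class's 0/1 indicator on all blocks.

    ``prob_blocks`` are the L cross-validated level-0 posterior matrices
    (each n x C).  Rank-deficient designs are fit with the minimal-norm
    solution (a warning is emitted).
    """
    X = _stack_blocks(prob_blocks)
    classes = sorted(set(true_labels))
    Y = np.array([[1.0 if y == c else 0.0 for c in classes] for y in true_labels])
    design = np.hstack([np.ones((X.shape[0], 1)), X])
    coef, _, rank, _ = np.linalg.lstsq(design, Y, rcond=None)
    if rank < design.shape[1]:
        warnings.warn(
            f"stack-1 design is rank deficient (rank {rank} < {design.shape[1]}); "
            "using the minimal-norm least-squares solution",
            stacklevel=2,
        )
    return Stack1Model(classes=classes, coef=coef)


def stack1_predict(model: Stack1Model, prob_blocks: Sequence[np.ndarray]) -> list[str]:
    X = _stack_blocks(prob_blocks)
    design = np.hstack([np.ones((X.shape[0], 1)), X])
    fitted = design @ model.coef
    return [model.classes[j] for j in np.argmax(fitted, axis=1)]


@dataclass
class Stack2Model:
    """Random-forest meta-classifier over probabilities + one-hot predictions."""

    classes: list[str]
    pred_classes: list[str]  # one-hot layout for predicted-class features
    forest: RandomForestClassifier


def _stack2_design(
    prob_blocks: Sequence[np.ndarray],
    pred_blocks: Sequence[Sequence[str]],
    pred_classes: list[str],
) -> np.ndarray:
    X = _stack_blocks(prob_blocks)
    onehots = []
    for preds in pred_blocks:
        oh = np.zeros((len(preds), len(pred_classes)))
        col = {c: j for j, c in enumerate(pred_classes)}
        for i, p in enumerate(preds):
            if p in col:
                oh[i, col[p]] = 1.0
        onehots.append(oh)
    return np.hstack([X] + onehots)


def stack2_fit(
    prob_blocks: Sequence[np.ndarray],
    pred_blocks: Sequence[Sequence[str]],
    true_labels: Sequence[str],
    seed: int = 0,
    n_estimators: int = 500,
) -> Stack2Model:
    classes = sorted(set(true_labels))
    pred_classes = sorted({p for preds in pred_blocks for p in preds} | set(classes))
    X = _stack2_design(prob_blocks, pred_blocks, pred_classes)
    forest = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    forest.fit(X, list(true_labels))
    return Stack2Model(classes=classes, pred_classes=pred_classes, forest=forest)


def stack2_predict(
    model: Stack2Model,
    prob_blocks: Sequence[np.ndarray],
    pred_blocks: Sequence[Sequence[str]],
) -> list[str]:
    X = _stack2_design(prob_blocks, pred_blocks, model.pred_classes)
    return [str(c) for c in model.forest.predict(X)]


def contribution_analysis(
    per_model_records: Sequence[Sequence[PredictionRecord]],
    precisions: Sequence[float],
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-model-out recall differences of PINCom at fixed precisions.

    Entry (model m, precision P0) = recall of the full L-model PINCom at P0
    minus recall of the PINCom built from the other L-1 models.  Negative
    values mean the combination does better without m.  NaN marks precision
    levels unreachable by either combination.
    """
    L = len(per_model_records)
    if L < 3:
        raise ValueError("contribution analysis needs at least 3 models")
    model_ids = [recs[0].model_id for recs in per_model_records]

    def recall_at(records_lists, P0):
        combined = combine_pin(records_lists, seed=seed)
        curve = rp_curve(combined_to_records(combined), "pin")
        try:
            return threshold_for_precision(curve, P0).recall
        except UnreachablePrecisionError:
            return np.nan

    full = {P0: recall_at(per_model_records, P0) for P0 in precisions}
    rows = {}
    for m in range(L):
        rest = [per_model_records[j] for j in range(L) if j != m]
        rows[model_ids[m]] = {
            P0: full[P0] - recall_at(rest, P0) for P0 in precisions
        }
    df = pd.DataFrame(rows).T
    df.index.name = "model_id"
    df.columns.name = "precision"
    return df
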