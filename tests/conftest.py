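from __future__ import annotations

import numpy as np
import pytest

from pincom.datatypes import LabeledDataset, PredictionRecord


def make_records(
    maxps,
    correct,
    model_id="m",
    classes=("A", "B"),
    pins=None,
    pred_classes=None,
):
    """Build a prediction-record table from score/correctness vectors.

    Correct records predict their own true class; incorrect ones predict
    the other class (or a supplied per-record class).
    """
    recs = []
    for i, (s, c) in enumerate(zip(maxps, correct)):
        true = classes[i % len(classes)]
        if pred_classes is not None:
            pred = pred_classes[i]
        else:
            pred = true if c else classes[(i + 1) % len(classes)]
        r = PredictionRecord(
            instance_id=f"x{i}",
            model_id=model_id,
            predicted_class=pred,
            true_class=true,
            maxp=float(s),
        )
        if pins is not None:
            r = r.with_pin(pins[i])
        recs.append(r)
    return recs


def calibrated_records(n, rng, model_id="m"):
    """Perfectly calibrated synthetic predictions: correctness ~ Bernoulli(MaxP)."""
    maxps = rng.uniform(0.3, 1.0, size=n)
    correct = rng.random(n) < maxps
    return make_records(maxps, correct, model_id=model_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def tiny_dataset():
    """3 well-separated 1-D classes, 12 instances."""
    rng = np.random.default_rng(7)
    means = {"a": -10.0, "b": 0.0, "c": 10.0}
    feats, labels, ids = [], [], []
    for cls, mu in means.items():
        for j in range(4):
            feats.append([rng.normal(mu, 0.1)])
            labels.append(cls)
            ids.append(f"{cls}{j}")
    return LabeledDataset(
        instance_ids=ids,
        features=np.array(feats),
        labels=np.array(labels, dtype=object),
        class_vocab=["a", "b", "c"],
    )
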