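"""Precision Index (PIN) and Class-Specific Precision Index (PIC).

A classifier's raw confidence — the maximum posterior probability MaxP — is
not comparable across learner families.  The tail precision

    Pindex(a) = precision of the prediction subset { x : MaxP(x) >= a }

is, and under the working assumption that higher confidence means higher
precision it is monotone non-decreasing in the threshold.  PIN is the
isotonic-regression fit of the observed per-record tail precisions on MaxP,
evaluated by linear interpolation between the distinct MaxP knots and
clamped to the endpoint values outside the observed range.  Being an
estimated precision, PIN lives on a common [0, 1] scale for every model and
is the quantity the combined classifier (PINCom) maximises over models.

PIC repeats the same tail-precision construction within one predicted class,
as a function of PIN: it captures that a model may classify a few classes
very well even when its overall precision curve saturates low.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .datatypes import (
    PosteriorMatrix,
    PredictionRecord,
    correctness_of,
)

logger = logging.getLogger(__name__)

MIN_CLASS_SUPPORT = 3  # below this, the per-class curve is a constant


def maxp_and_class(
    P: PosteriorMatrix, true_classes: Sequence[str] | None = None
) -> list[PredictionRecord]:
    """Extract predicted class (argmax) and MaxP from a posterior matrix.

    Argmax ties break toward the lowest class-vocabulary index.  Optionally
    attaches true classes, aligned by position.
    """
    if P.n == 0:
        return []
    if true_classes is not None and len(true_classes) != P.n:
        raise ValueError("true_classes length does not match posterior rows")
    idx = np.argmax(P.probs, axis=1)  # first max wins: the tie rule
    maxps = P.probs[np.arange(P.n), idx]
    return [
        PredictionRecord(
            instance_id=P.instance_ids[i],
            model_id=P.model_id,
            predicted_class=P.class_vocab[idx[i]],
            true_class=None if true_classes is None else true_classes[i],
            maxp=float(maxps[i]),
        )
        for i in range(P.n)
    ]


def tail_precision(scores: np.ndarray, correct: np.ndarray) -> np.ndarray:
    """Per-record tail precision: precision of { score >= score_i }.

    Records with equal scores receive equal values (the tail is a function
    of the threshold, not of the record).
    """
    scores = np.asarray(scores, dtype=float)
    correct = np.asarray(correct, dtype=float)
    if scores.size == 0:
        return np.empty(0)
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    c_cum = np.cumsum(correct[order])
    n_cum = np.arange(1, scores.size + 1, dtype=float)
    # index of the last record in each tie block = full tail count
    _, inverse, counts = np.unique(-s_sorted, return_inverse=True, return_counts=True)
    last_in_block = np.cumsum(counts) - 1
    prec_sorted = (c_cum[last_in_block] / n_cum[last_in_block])[inverse]
    out = np.empty_like(prec_sorted)
    out[order] = prec_sorted
    return out


def observed_pindex(records: Sequence[PredictionRecord]) -> np.ndarray:
    """Observed Pindex(MaxP(x_i)) for each record, aligned with the input."""
    if not records:
        raise ValueError("need at least one record")
    scores = np.array([r.maxp for r in records], dtype=float)
    return tail_precision(scores, correctness_of(records))


def _isotonic_knots(
    x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted non-decreasing least-squares fit on pooled distinct x.

    Records tied in x share the same target (tail precisions are functions
    of the threshold), so pooling to one knot per distinct value with weight
    = multiplicity reproduces the record-level isotonic fit exactly.
    """
    knots, inverse, counts = np.unique(x, return_inverse=True, return_counts=True)
    targets = np.empty(knots.size)
    targets[inverse] = y  # tied records carry identical y
    if knots.size == 1:
        return knots, targets
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fitted = iso.fit_transform(knots, targets, sample_weight=counts)
    return knots, np.asarray(fitted, dtype=float)


@dataclass
class PinFunction:
    """Monotone non-decreasing map MaxP -> PIN for one model.

    Piecewise-linear between knots, clamped to endpoint values outside the
    observed MaxP range.
    """

    model_id: str
    knots: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.knots.size == 0:
            raise ValueError("PinFunction needs at least one knot")
        if self.knots.size != self.values.size:
            raise ValueError("knots and values differ in length")
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        if np.any(np.diff(self.values) < -1e-12):
            raise ValueError("fitted values must be non-decreasing")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("fitted values outside [0, 1]")

    def __call__(self, maxp):
        arr = np.asarray(maxp, dtype=float)
        out = np.interp(arr, self.knots, self.values)  # interp clamps outside
        return float(out) if np.isscalar(maxp) else out

    def to_json(self) -> str:
        return json.dumps(
            {
                "model_id": self.model_id,
                "knots": self.knots.tolist(),
                "values": self.values.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PinFunction":
        d = json.loads(text)
        return cls(d["model_id"], np.array(d["knots"]), np.array(d["values"]))


def fit_pin(records: Sequence[PredictionRecord]) -> PinFunction:
    """Fit the PIN function from scored predictions with known truth.

    Isotonic (non-decreasing, weighted least squares) regression of the
    observed tail precisions Pindex(MaxP(x_i)) on MaxP(x_i); ties in MaxP
    pooled to a single knot weighted by multiplicity.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to fit a PIN function")
    scores = np.array([r.maxp for r in records], dtype=float)
    pindex = tail_precision(scores, correctness_of(records))
    knots, values = _isotonic_knots(scores, pindex)
    return PinFunction(records[0].model_id, knots, values)


def eval_pin(f: PinFunction, maxp):
    """Evaluate a fitted PIN function (scalar or vector)."""
    return f(maxp)


def attach_pins(
    records: Sequence[PredictionRecord], f: PinFunction
) -> list[PredictionRecord]:
    """Return copies of the records with PIN = f(MaxP) filled in."""
    return [r.with_pin(f(r.maxp)) for r in records]


@dataclass
class PicFunction:
    """Per-predicted-class monotone maps PIN -> class-specific precision.

    Classes with fewer than ``MIN_CLASS_SUPPORT`` predictions get a constant
    curve equal to their class precision.  Classes never predicted at
    training time fall back, with a warning, to returning the PIN unchanged.
    """

    model_id: str
    curves: dict[str, PinFunction] = field(default_factory=dict)

    def __call__(self, predicted_class: str, pin: float) -> float:
        if predicted_class not in self.curves:
            logger.warning(
                "model %s: class %r unseen among training predictions; "
                "PIC falls back to PIN",
                self.model_id,
                predicted_class,
            )
            return float(pin)
        return float(self.curves[predicted_class](pin))

    def to_json(self) -> str:
        return json.dumps(
            {
                "model_id": self.model_id,
                "curves": {
                    k: {"knots": f.knots.tolist(), "values": f.values.tolist()}
                    for k, f in self.curves.items()
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PicFunction":
        d = json.loads(text)
        return cls(
            d["model_id"],
            {
                k: PinFunction(d["model_id"], np.array(c["knots"]), np.array(c["values"]))
                for k, c in d["curves"].items()
            },
        )


def fit_pic(records: Sequence[PredictionRecord]) -> PicFunction:
    """Fit class-specific precision curves over the PIN scale.

    For each predicted class k, the tail precision of
    { x : predicted(x) = k, PIN(x) >= a } is regressed isotonically on the
    PIN knots, exactly as in :func:`fit_pin` but restricted to the class and
    with PIN as the abscissa.
    """
    if not records:
        raise ValueError("need records to fit PIC")
    pins = np.array([r.pin for r in records], dtype=float)
    if np.isnan(pins).any():
        raise ValueError("all records must carry PIN before fitting PIC")
    model_id = records[0].model_id
    curves: dict[str, PinFunction] = {}
    by_class: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_class.setdefault(r.predicted_class, []).append(i)
    correct = correctness_of(records)
    for cls, idx in by_class.items():
        idx = np.asarray(idx)
        cls_pins, cls_corr = pins[idx], correct[idx]
        if idx.size < MIN_CLASS_SUPPORT:
            prec = float(np.mean(cls_corr))
            curves[cls] = PinFunction(model_id, [0.5], [prec])
            continue
        pk = tail_precision(cls_pins, cls_corr)
        knots, values = _isotonic_knots(cls_pins, pk)
        curves[cls] = PinFunction(model_id, knots, values)
    return PicFunction(model_id, curves)


def eval_pic(g: PicFunction, predicted_class: str, pin: float) -> float:
    """PIC(x) = class-specific precision curve of the predicted class at PIN."""
    return g(predicted_class, pin)


def attach_pics(
    records: Sequence[PredictionRecord], g: PicFunction
) -> list[PredictionRecord]:
    """Return copies of the records with PIC = g(class, PIN) filled in."""
    return [r.with_pic(g(r.predicted_class, r.pin)) for r in records]
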