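"""Uniform contract over heterogeneous base classifiers.

Any learner that estimates class-membership probabilities can participate in
the precision-index framework.  This module provides:

* a pluggable registry of learner factories (random forest, radial SVM,
  multilayer-perceptron "neural network", k-nearest-neighbour with
  vote-fraction probabilities, multi-response linear regression, Gaussian
  naive Bayes, linear discriminant analysis);
* :func:`oversample`, duplicating small classes up to the largest class size;
* :func:`average_runs`, averaging the posterior matrices of repeated fits of
  an unstable learner (the classical stabilisation for neural nets);
* :func:`fit_predict_proba`, the single entry point the protocols use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .datatypes import AlignmentError, LabeledDataset, PosteriorMatrix

PROB_FLOOR = 1e-12


class ConfigurationError(ValueError):
    """Bad classifier specification (unknown kind, invalid params)."""


@dataclass
class ClassifierSpec:
    """Declarative description of one base classifier.

    ``kind`` selects a factory from the registry; ``params`` are passed
    through to it.  ``oversample`` trains on the class-balanced duplicate of
    the training data.  ``n_averaged_runs`` refits the learner that many
    times with distinct seeds and averages the posterior matrices.
    """

    model_id: str
    kind: str
    params: dict = field(default_factory=dict)
    oversample: bool = False
    n_averaged_runs: int = 1
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_averaged_runs < 1:
            raise ConfigurationError("n_averaged_runs must be >= 1")


class _MultiResponseLinearClassifier(BaseEstimator, ClassifierMixin):
    """Least-squares regression of per-class 0/1 indicators.

    Fitted responses are clipped to [0, 1] and renormalised into a
    probability row; a uniform row substitutes when all responses clip to 0.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        Y = np.zeros((X.shape[0], len(self.classes_)))
        Y[np.arange(X.shape[0]), y_idx] = 1.0
        design = np.hstack([np.ones((X.shape[0], 1)), X])
        self.coef_, *_ = np.linalg.lstsq(design, Y, rcond=None)
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        design = np.hstack([np.ones((X.shape[0], 1)), X])
        fitted = np.clip(design @ self.coef_, 0.0, 1.0)
        sums = fitted.sum(axis=1, keepdims=True)
        flat = sums[:, 0] <= 0
        fitted[flat] = 1.0
        sums[flat] = fitted.shape[1]
        return fitted / sums

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def _make_rf(seed: int, **params):
    params.setdefault("n_estimators", 500)
    return RandomForestClassifier(random_state=seed, **params)


def _make_svm(seed: int, **params):
    params.setdefault("kernel", "rbf")
    params.setdefault("probability", True)
    return SVC(random_state=seed, **params)


def _make_nn(seed: int, **params):
    params.setdefault("hidden_layer_sizes", (10,))
    params.setdefault("max_iter", 500)
    return MLPClassifier(random_state=seed, **params)


def _make_knn(seed: int, **params):
    # neighbour vote fractions ARE the probabilities; seed unused
    params.setdefault("n_neighbors", 6)
    return KNeighborsClassifier(**params)


def _make_mlr(seed: int, **params):
    return _MultiResponseLinearClassifier(**params)


def _make_gnb(seed: int, **params):
    return GaussianNB(**params)


def _make_lda(seed: int, **params):
    return LinearDiscriminantAnalysis(**params)


LEARNER_REGISTRY: dict[str, Callable] = {
    "rf": _make_rf,
    "svm": _make_svm,
    "nn": _make_nn,
    "knn": _make_knn,
    "mlr": _make_mlr,
    "gnb": _make_gnb,
    "lda": _make_lda,
}


def register_learner(kind: str, factory: Callable) -> None:
    """Register ``factory(seed, **params) -> estimator`` under ``kind``."""
    LEARNER_REGISTRY[kind] = factory


def oversample(train: LabeledDataset) -> LabeledDataset:
    """Duplicate small classes up to the largest class size.

    Each class is repeated by whole copies, topped up with its first
    ``size_max mod size_k`` instances in original order, so every class
    count equals the original maximum.  Idempotent.
    """
    if train.n == 0:
        raise ValueError("cannot oversample an empty dataset")
    counts = train.class_counts()
    size_max = max(counts.values())
    if all(v == size_max for v in counts.values()):
        return train
    keep: list[int] = []
    for cls in train.class_vocab:
        cls_idx = np.flatnonzero(train.labels == cls)
        n_k = len(cls_idx)
        full, extra = divmod(size_max, n_k)
        keep.extend(np.concatenate([np.tile(cls_idx, full), cls_idx[:extra]]))
    return LabeledDataset(
        instance_ids=[train.instance_ids[i] for i in keep],
        features=train.features[keep],
        labels=train.labels[np.asarray(keep, dtype=int)],
        class_vocab=list(train.class_vocab),
    )


def average_runs(runs: Sequence[PosteriorMatrix]) -> PosteriorMatrix:
    """Element-wise mean of aligned posterior matrices from repeated runs."""
    if not runs:
        raise ValueError("no runs to average")
    first = runs[0]
    for r in runs[1:]:
        if r.model_id != first.model_id:
            raise AlignmentError("runs come from different models")
        if r.instance_ids != first.instance_ids:
            raise AlignmentError("runs cover different instances or orders")
        if r.class_vocab != first.class_vocab:
            raise AlignmentError("runs use different class alignments")
        if r.probs.shape != first.probs.shape:
            raise AlignmentError("runs have mismatched shapes")
    mean = np.mean([r.probs for r in runs], axis=0)
    return PosteriorMatrix(
        model_id=first.model_id,
        instance_ids=list(first.instance_ids),
        probs=mean,
        class_vocab=list(first.class_vocab),
    )


def _floor_and_renormalize(probs: np.ndarray) -> np.ndarray:
    probs = np.clip(probs, PROB_FLOOR, 1.0)
    return probs / probs.sum(axis=1, keepdims=True)


def _align_to_vocab(
    probs: np.ndarray, fitted_classes: Sequence[str], class_vocab: Sequence[str]
) -> np.ndarray:
    """Expand an estimator's probability columns onto the full vocabulary."""
    out = np.zeros((probs.shape[0], len(class_vocab)))
    col = {c: j for j, c in enumerate(class_vocab)}
    for j_src, cls in enumerate(fitted_classes):
        out[:, col[cls]] = probs[:, j_src]
    return out


def fit_predict_proba(
    spec: ClassifierSpec,
    train: LabeledDataset,
    eval_features: np.ndarray,
    eval_ids: Sequence[str] | None = None,
) -> PosteriorMatrix:
    """Fit the specified learner and return posterior probabilities.

    Deterministic given ``spec.random_seed``.  With ``n_averaged_runs > 1``
    the learner is refit with seeds ``seed, seed+1, ...`` and the posterior
    matrices averaged.  Probabilities are floored at 1e-12 and renormalised
    so every row is a valid distribution.
    """
    eval_features = np.asarray(eval_features, dtype=float)
    if eval_features.ndim != 2 or eval_features.shape[1] != train.d:
        raise AlignmentError(
            f"eval features have {eval_features.shape} but training data has "
            f"{train.d} columns"
        )
    if spec.kind not in LEARNER_REGISTRY:
        raise ConfigurationError(
            f"unknown learner kind {spec.kind!r}; known: {sorted(LEARNER_REGISTRY)}"
        )
    data = oversample(train) if spec.oversample else train
    vocab = data.class_vocab
    if eval_ids is not None:
        if len(eval_ids) != eval_features.shape[0]:
            raise AlignmentError("eval_ids length does not match eval_features")
        ids = list(eval_ids)
    else:
        ids = [f"x{i}" for i in range(eval_features.shape[0])]

    if len(vocab) == 1:
        probs = np.ones((eval_features.shape[0], 1))
        return PosteriorMatrix(spec.model_id, ids, probs, list(vocab))

    singletons = [c for c, k in data.class_counts().items() if k < 2]

    runs = []
    for run in range(spec.n_averaged_runs):
        est = LEARNER_REGISTRY[spec.kind](spec.random_seed + run, **dict(spec.params))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(data.features, data.labels.astype(str))
                raw = est.predict_proba(eval_features)
        except Exception as exc:  # pragma: no cover - learner-specific
            if singletons:
                raise ValueError(
                    f"learner {spec.kind!r} failed on training classes with a "
                    f"single instance: {singletons}"
                ) from exc
            raise
        probs = _align_to_vocab(raw, [str(c) for c in est.classes_], vocab)
        runs.append(
            PosteriorMatrix(spec.model_id, ids, _floor_and_renormalize(probs), list(vocab))
        )
    return average_runs(runs)
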