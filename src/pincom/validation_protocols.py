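"""Resampling protocols for fitting and honestly evaluating PIN functions.

Two layered protocols:

* **Training/test construction** — repeated 10-fold cross-validation on the
  training data produces, for each model, K x n out-of-fold predictions on
  which the PIN function is fitted (stage A1); models are then refit on the
  full training data, the fitted PIN functions map their test-set MaxP
  values onto the common precision scale, and the combined classifier picks
  the highest PIN per test instance (stage A2).

* **Double cross-validation** — because a PIN function fitted on the same
  predictions it scores is optimistically biased, evaluation wraps an outer
  10-fold loop around the whole of stage A1: for each outer fold, PIN
  functions and the combined rule are built from repeated inner CV on the
  remaining 90% only, then applied to the held-out 10%.  The full pass is
  repeated KK times, giving KK x n predictions per model (and for the
  combined classifier) in which no instance ever influenced its own
  calibration.

When test-set truth is unknown, the double-cross-validated precision
curves from the training data stand in for the unobservable test precision:
the estimated number of correct test predictions above a threshold is the
subset size times the cross-validated precision at that threshold
(class-by-class when thresholding on PIC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier_layer import ClassifierSpec, fit_predict_proba
from .datatypes import LabeledDataset, PredictionRecord
from .pincom_combiner import (
    PINCOM_ID,
    CombinedPrediction,
    combine_pin,
    combined_to_records,
)
from .precision_index import (
    PicFunction,
    PinFunction,
    attach_pics,
    attach_pins,
    fit_pic,
    fit_pin,
    maxp_and_class,
)
from .pr_curves import class_rp_curve, rp_curve

logger = logging.getLogger(__name__)


@dataclass
class CVConfig:
    """Cross-validation design: folds, repeat counts, seeding.

    ``K`` repeats the fold partition for PIN estimation (the study design
    uses 20, and accepts 20-50); ``KK`` repeats the full outer double-CV
    pass (study design: 10).  Stratified folds are the default so that
    classes as small as 8 instances appear in every training split; set
    ``stratified=False`` for literal unstratified random partitions.
    """

    n_folds: int = 10
    K: int = 20
    KK: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.K < 1 or self.KK < 1:
            raise ValueError("repeat counts must be >= 1")


@dataclass
class CVPredictionSet:
    """Out-of-fold predictions from one model across repeats.

    ``provenance[i] = (repeat, fold)`` for ``records[i]``; ``probs`` keeps
    the full posterior rows (aligned to the training class vocabulary) for
    the stacking combiners.
    """

    model_id: str
    records: list[PredictionRecord]
    provenance: list[tuple[int, int]]
    probs: np.ndarray  # (len(records), C)
    class_vocab: list[str]


def _partition(
    labels: np.ndarray, n_folds: int, rng: np.random.Generator, stratified: bool
) -> list[np.ndarray]:
    """Random disjoint folds covering all indices.

    Stratified variant deals each class's shuffled indices round-robin into
    folds from a random starting offset, so every fold's complement keeps
    at least one instance of every class of size >= 2.
    """
    n = len(labels)
    if not stratified:
        perm = rng.permutation(n)
        return [np.sort(f) for f in np.array_split(perm, n_folds)]
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        start = int(rng.integers(n_folds))
        for j, i in enumerate(idx):
            folds[(start + j) % n_folds].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _check_cv_inputs(train: LabeledDataset, cfg: CVConfig) -> None:
    if train.n < cfg.n_folds:
        raise ValueError(
            f"dataset of {train.n} instances cannot be split into "
            f"{cfg.n_folds} folds"
        )
    small = [c for c, k in train.class_counts().items() if k < 2]
    if small:
        raise ValueError(f"classes with fewer than 2 instances: {small}")


def cv_level0(
    models: Sequence[ClassifierSpec],
    train: LabeledDataset,
    cfg: CVConfig,
    K: int | None = None,
) -> dict[str, CVPredictionSet]:
    """K repeats of n-fold CV: out-of-fold MaxP and predicted class per model.

    All models see identical partitions (paired design); output size is
    exactly K x n records per model.
    """
    _check_cv_inputs(train, cfg)
    K = cfg.K if K is None else K
    part_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    out: dict[str, CVPredictionSet] = {
        m.model_id: CVPredictionSet(
            m.model_id, [], [], np.empty((0, train.n_classes)), list(train.class_vocab)
        )
        for m in models
    }
    prob_rows: dict[str, list[np.ndarray]] = {m.model_id: [] for m in models}
    vocab_col = {c: j for j, c in enumerate(train.class_vocab)}
    for rep in range(K):
        folds = _partition(train.labels, cfg.n_folds, part_rng, cfg.stratified)
        for f, hold in enumerate(folds):
            if hold.size == 0:
                continue
            fit_idx = np.setdiff1d(np.arange(train.n), hold)
            sub = train.subset(fit_idx)
            hold_ids = [train.instance_ids[i] for i in hold]
            hold_truth = [str(t) for t in train.labels[hold]]
            for m, spec in enumerate(models):
                run_seed = int(
                    np.random.SeedSequence(
                        [cfg.seed, 13, spec.random_seed, rep, f]
                    ).generate_state(1)[0] % (2**31)
                )
                P = fit_predict_proba(
                    ClassifierSpec(
                        spec.model_id, spec.kind, dict(spec.params),
                        spec.oversample, spec.n_averaged_runs, run_seed,
                    ),
                    sub,
                    train.features[hold],
                    eval_ids=hold_ids,
                )
                recs = maxp_and_class(P, hold_truth)
                out[spec.model_id].records.extend(recs)
                out[spec.model_id].provenance.extend([(rep, f)] * len(recs))
                # align probability rows to the full vocabulary
                full = np.zeros((P.n, train.n_classes))
                for j, c in enumerate(P.class_vocab):
                    full[:, vocab_col[c]] = P.probs[:, j]
                prob_rows[spec.model_id].append(full)
    for mid in out:
        out[mid].probs = np.vstack(prob_rows[mid])
    return out


@dataclass
class A1Result:
    pin_functions: dict[str, PinFunction]
    pic_functions: dict[str, PicFunction]
    per_model_records: dict[str, list[PredictionRecord]]  # with PIN and PIC
    combined: list[CombinedPrediction]
    combined_records: list[PredictionRecord]


def estimate_pins_A1(
    cv_sets: dict[str, CVPredictionSet], seed: int = 0
) -> A1Result:
    """Fit each model's PIN (and PIC) on its pooled cross-validated
    predictions, then form the combined classifier's training predictions."""
    pin_functions, pic_functions, per_model = {}, {}, {}
    for mid, cvs in cv_sets.items():
        f = fit_pin(cvs.records)
        pin_functions[mid] = f
        scored = attach_pins(cvs.records, f)
        g = fit_pic(scored)
        pic_functions[mid] = g
        per_model[mid] = attach_pics(scored, g)
    model_ids = list(cv_sets)
    if len(model_ids) >= 2:
        combined = combine_pin([per_model[m] for m in model_ids], seed=seed)
        combined_records = combined_to_records(combined)
        g_c = fit_pic(combined_records)
        pic_functions[PINCOM_ID] = g_c
        combined_records = attach_pics(combined_records, g_c)
    else:
        combined, combined_records = [], []
    return A1Result(pin_functions, pic_functions, per_model, combined, combined_records)


@dataclass
class A2Result:
    per_model_records: dict[str, list[PredictionRecord]]
    combined: list[CombinedPrediction]
    combined_records: list[PredictionRecord]


def apply_A2(
    models: Sequence[ClassifierSpec],
    train: LabeledDataset,
    test_features: np.ndarray,
    pin_functions: dict[str, PinFunction],
    seed: int = 0,
    test_ids: Sequence[str] | None = None,
    test_truth: Sequence[str] | None = None,
    pic_functions: dict[str, PicFunction] | None = None,
) -> A2Result:
    """Refit on the full training data, score the test set, map MaxP -> PIN
    through the training-fitted PIN functions, and combine by maximum PIN."""
    per_model: dict[str, list[PredictionRecord]] = {}
    for spec in models:
        P = fit_predict_proba(spec, train, test_features, eval_ids=test_ids)
        recs = maxp_and_class(P, list(test_truth) if test_truth is not None else None)
        scored = attach_pins(recs, pin_functions[spec.model_id])
        if pic_functions is not None and spec.model_id in pic_functions:
            scored = attach_pics(scored, pic_functions[spec.model_id])
        per_model[spec.model_id] = scored
    if len(models) >= 2:
        combined = combine_pin([per_model[m.model_id] for m in models], seed=seed)
        combined_records = combined_to_records(combined)
        if pic_functions is not None and PINCOM_ID in pic_functions:
            combined_records = attach_pics(combined_records, pic_functions[PINCOM_ID])
    else:
        only = models[0].model_id
        combined, combined_records = [], list(per_model[only])
    return A2Result(per_model, combined, combined_records)


@dataclass
class DoubleCVResult:
    """KK x n double-cross-validated predictions per model and for PINCom."""

    per_model_records: dict[str, list[PredictionRecord]]
    combined_records: list[PredictionRecord]
    provenance: list[tuple[int, int]]  # (outer repeat kk, outer fold)
    audit: list[dict]  # per (kk, fold): calibration vs holdout instance ids


def double_cv(
    models: Sequence[ClassifierSpec],
    train: LabeledDataset,
    cfg: CVConfig,
    max_fits: int | None = 100_000,
) -> DoubleCVResult:
    """Outer 10-fold CV around the full PIN-estimation stage.

    For each outer fold: inner K-repeat CV on the remaining 90% fits the
    PIN functions and the combined rule without touching the held-out 10%;
    outer-fold models trained on the 90% then score the 10%, the inner PIN
    functions calibrate them, and the combined prediction is formed.  The
    whole pass repeats KK times.
    """
    _check_cv_inputs(train, cfg)
    n_fits = cfg.KK * cfg.n_folds * (cfg.K * cfg.n_folds + 1) * len(models)
    if max_fits is not None and n_fits > max_fits:
        logger.warning(
            "double CV will perform %d model fits (KK=%d, K=%d, %d folds, "
            "%d models)", n_fits, cfg.KK, cfg.K, cfg.n_folds, len(models),
        )
    outer_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 17]))
    per_model: dict[str, list[PredictionRecord]] = {m.model_id: [] for m in models}
    combined_records: list[PredictionRecord] = []
    provenance: list[tuple[int, int]] = []
    audit: list[dict] = []
    for kk in range(cfg.KK):
        folds = _partition(train.labels, cfg.n_folds, outer_rng, cfg.stratified)
        for f, hold in enumerate(folds):
            if hold.size == 0:
                continue
            fit_idx = np.setdiff1d(np.arange(train.n), hold)
            inner_train = train.subset(fit_idx)
            inner_seed = int(
                np.random.SeedSequence([cfg.seed, 19, kk, f]).generate_state(1)[0]
                % (2**31)
            )
            inner_cfg = CVConfig(
                n_folds=cfg.n_folds, K=cfg.K, KK=1,
                seed=inner_seed, stratified=cfg.stratified,
            )
            inner_sets = cv_level0(models, inner_train, inner_cfg)
            a1 = estimate_pins_A1(inner_sets, seed=inner_seed)
            a2 = apply_A2(
                models,
                inner_train,
                train.features[hold],
                a1.pin_functions,
                seed=inner_seed + 1,
                test_ids=[train.instance_ids[i] for i in hold],
                test_truth=[str(t) for t in train.labels[hold]],
                pic_functions=a1.pic_functions,
            )
            for m in models:
                per_model[m.model_id].extend(a2.per_model_records[m.model_id])
            combined_records.extend(a2.combined_records)
            provenance.extend([(kk, f)] * hold.size)
            audit.append(
                {
                    "kk": kk,
                    "fold": f,
                    "calibration_ids": set(inner_train.instance_ids),
                    "holdout_ids": {train.instance_ids[i] for i in hold},
                }
            )
    return DoubleCVResult(per_model, combined_records, provenance, audit)


def estimate_test_pr(
    test_records: Sequence[PredictionRecord],
    xv_records: Sequence[PredictionRecord],
    thresholds: Sequence[float],
    score: str = "pin",
) -> pd.DataFrame:
    """Estimate test-set precision/recall when test truth is unknown.

    The double-cross-validated training predictions supply the precision
    curves.  Thresholding on PIN: estimated correct in { PIN >= a } is the
    subset size times the cross-validated smoothed precision P_xv(a).
    Thresholding on PIC: per predicted class k, estimated correct is
    |{ PIC >= a, predicted = k }| times the class-specific cross-validated
    precision P_k(a), summed over classes.
    """
    score = score.lower()
    if score not in ("pin", "pic"):
        raise ValueError("score must be 'pin' or 'pic'")
    n_test = len(test_records)
    if n_test == 0:
        raise ValueError("no test records")
    test_scores = np.array([getattr(r, score) for r in test_records], dtype=float)
    if np.isnan(test_scores).any():
        raise ValueError(f"test records missing {score} values")

    rows = []
    if score == "pin":
        curve = rp_curve(xv_records, "pin")
        for a in thresholds:
            size = int(np.sum(test_scores >= a))
            if size == 0:
                rows.append((a, 0, np.nan, np.nan, 0.0))
                continue
            p = float(curve.precision_at(a))
            est = size * p
            rows.append((a, size, est, p, est / n_test))
    else:
        overall = rp_curve(xv_records, "pic")
        xv_classes = {r.predicted_class for r in xv_records}
        class_curves = {}
        for k in xv_classes:
            try:
                class_curves[k] = class_rp_curve(xv_records, k, "pic")
            except ValueError:
                pass  # no truly-k instance in the CV set: use overall curve
        test_classes = np.array([r.predicted_class for r in test_records], dtype=object)
        for a in thresholds:
            in_set = test_scores >= a
            size = int(in_set.sum())
            if size == 0:
                rows.append((a, 0, np.nan, np.nan, 0.0))
                continue
            est = 0.0
            for k in np.unique(test_classes[in_set]):
                n_k = int(np.sum(in_set & (test_classes == k)))
                c = class_curves.get(k, overall)
                if k not in class_curves:
                    logger.warning(
                        "class %r absent from cross-validated predictions; "
                        "using the overall PIC curve", k,
                    )
                est += n_k * float(c.precision_at(a))
            rows.append((a, size, est, est / size, est / n_test))
    return pd.DataFrame(
        rows, columns=["a", "subset_size", "est_correct", "P", "R"]
    )
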