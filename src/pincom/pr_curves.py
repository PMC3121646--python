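"""Recall–Precision curves over confidence thresholds, with inversion.

For a confidence score s (MaxP, PIN, MaxPIN or PIC) and threshold a,

    P(a) = correct in { s >= a } / |{ s >= a }|
    R(a) = correct in { s >= a } / n_total

On the raw step curves P(0) and R(0) coincide exactly: both are the overall
precision of the full prediction set.  The smoothed curves are the isotonic
(P, non-decreasing) and antitonic (R, non-increasing) least-squares fits
with linear interpolation, which is what threshold inversion operates on;
pooling can move the smoothed value at the lowest knot off the raw full-set
value, so the full-set identity is a property of the raw curves.  Inversion for a target
precision returns the *smallest* qualifying threshold — the largest
prediction subset achieving that precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .datatypes import PredictionRecord, correctness_of, scores_of
from .precision_index import _isotonic_knots


class UnreachablePrecisionError(ValueError):
    def __init__(self, target: float, achievable: float):
        self.target, self.achievable = target, achievable
        super().__init__(
            f"target precision {target:.4f} exceeds the curve's maximum "
            f"achievable smoothed precision {achievable:.4f}"
        )


class UnreachableRecallError(ValueError):
    def __init__(self, target: float, achievable: float):
        self.target, self.achievable = target, achievable
        super().__init__(
            f"target recall {target:.4f} exceeds the full-set recall "
            f"{achievable:.4f}"
        )


@dataclass
class RPCurve:
    """Raw and monotone-smoothed precision/recall as functions of threshold.

    ``thresholds`` are the distinct observed scores; evaluation outside
    their range clamps, so ``precision_at(0)`` is the full-set precision.
    """

    score_name: str
    thresholds: np.ndarray
    p_raw: np.ndarray
    r_raw: np.ndarray
    p_smooth: np.ndarray
    r_smooth: np.ndarray
    n_total: int
    weights: np.ndarray  # score multiplicity at each threshold

    @property
    def overall_precision(self) -> float:
        """Raw precision of the full prediction set (threshold 0)."""
        return float(self.p_raw[0])

    @property
    def overall_recall(self) -> float:
        """Raw recall of the full prediction set (threshold 0)."""
        return float(self.r_raw[0])

    def precision_at(self, a) -> np.ndarray | float:
        out = np.interp(np.asarray(a, dtype=float), self.thresholds, self.p_smooth)
        return float(out) if np.isscalar(a) else out

    def recall_at(self, a) -> np.ndarray | float:
        out = np.interp(np.asarray(a, dtype=float), self.thresholds, self.r_smooth)
        return float(out) if np.isscalar(a) else out

    def subset_size_at(self, a: float, scores: np.ndarray | None = None) -> int:
        if scores is None:
            # reconstruct counts from stored multiplicities
            return int(self.weights[self.thresholds >= a].sum())
        return int(np.sum(np.asarray(scores) >= a))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "a": self.thresholds,
                "P_raw": self.p_raw,
                "R_raw": self.r_raw,
                "P_smooth": self.p_smooth,
                "R_smooth": self.r_smooth,
            }
        )


@dataclass
class ThresholdResult:
    threshold: float
    precision: float
    recall: float
    subset_size: int


def _raw_tail_curves(
    scores: np.ndarray, correct: np.ndarray, n_total: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Step-function P(a), R(a) on the distinct observed scores."""
    order = np.argsort(scores, kind="stable")
    s = scores[order]
    c = correct[order].astype(float)
    knots, first_idx, counts = np.unique(s, return_index=True, return_counts=True)
    # tail sums: correct and count among scores >= each knot
    c_rev_cum = np.cumsum(c[::-1])[::-1]
    tail_correct = c_rev_cum[first_idx]
    tail_count = len(s) - first_idx
    P = tail_correct / tail_count
    R = tail_correct / n_total
    return knots, P, R, counts.astype(float)


def rp_curve(
    records: Sequence[PredictionRecord], score_name: str
) -> RPCurve:
    """Overall Recall–Precision curve of a scored prediction table."""
    if not records:
        raise ValueError("cannot build a curve from an empty record set")
    scores = scores_of(records, score_name)
    correct = correctness_of(records)
    return _build_curve(score_name, scores, correct, n_total=len(records))


def class_rp_curve(
    records: Sequence[PredictionRecord], cls: str, score_name: str
) -> RPCurve:
    """Class-specific curve: precision within predictions assigned to ``cls``,
    recall relative to all instances whose true class is ``cls``."""
    pred_mask = np.array([r.predicted_class == cls for r in records])
    if not pred_mask.any():
        raise ValueError(f"no record is predicted to class {cls!r}")
    n_true = sum(r.true_class == cls for r in records)
    if n_true == 0:
        raise ValueError(f"no record has true class {cls!r}; recall undefined")
    sub = [r for r, m in zip(records, pred_mask) if m]
    scores = scores_of(sub, score_name)
    correct = correctness_of(sub)
    return _build_curve(score_name, scores, correct, n_total=n_true)


def _build_curve(
    score_name: str, scores: np.ndarray, correct: np.ndarray, n_total: int
) -> RPCurve:
    knots, P, R, w = _raw_tail_curves(scores, correct, n_total)
    if knots.size == 1:
        p_s, r_s = P.copy(), R.copy()
    else:
        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
        p_s = np.asarray(iso.fit_transform(knots, P, sample_weight=w))
        anti = IsotonicRegression(increasing=False, out_of_bounds="clip")
        r_s = np.asarray(anti.fit_transform(knots, R, sample_weight=w))
    return RPCurve(
        score_name=score_name,
        thresholds=knots,
        p_raw=P,
        r_raw=R,
        p_smooth=p_s,
        r_smooth=r_s,
        n_total=n_total,
        weights=w,
    )


def threshold_for_precision(curve: RPCurve, P0: float) -> ThresholdResult:
    """Smallest threshold whose smoothed precision reaches ``P0``.

    Inverse linear interpolation on the smoothed (non-decreasing) precision
    curve; the result is the largest prediction subset at the target
    precision.
    """
    if not 0.0 <= P0 <= 1.0:
        raise ValueError("target precision must lie in [0, 1]")
    p = curve.p_smooth
    pmax = float(p[-1])
    if P0 > pmax:
        raise UnreachablePrecisionError(P0, pmax)
    if P0 <= p[0]:
        a0 = 0.0
    else:
        j = int(np.searchsorted(p, P0, side="left"))  # first knot with p >= P0
        lo, hi = curve.thresholds[j - 1], curve.thresholds[j]
        plo, phi = p[j - 1], p[j]
        a0 = float(lo) if phi == plo else float(lo + (P0 - plo) / (phi - plo) * (hi - lo))
    return ThresholdResult(
        threshold=a0,
        precision=float(curve.precision_at(a0)),
        recall=float(curve.recall_at(a0)),
        subset_size=curve.subset_size_at(a0),
    )


def threshold_for_recall(curve: RPCurve, R0: float) -> ThresholdResult:
    """Largest threshold whose smoothed recall still reaches ``R0``."""
    r = curve.r_smooth
    r_full = float(r[0])
    if R0 < 0:
        raise ValueError("target recall must be non-negative")
    if R0 > r_full:
        raise UnreachableRecallError(R0, r_full)
    if R0 <= r[-1]:
        a0 = float(curve.thresholds[-1])
    else:
        # r is non-increasing: find last knot with r >= R0
        j = int(np.searchsorted(-r, -R0, side="right"))  # first knot with r < R0
        lo, hi = curve.thresholds[j - 1], curve.thresholds[j]
        rlo, rhi = r[j - 1], r[j]
        a0 = float(lo) if rlo == rhi else float(lo + (rlo - R0) / (rlo - rhi) * (hi - lo))
    return ThresholdResult(
        threshold=a0,
        precision=float(curve.precision_at(a0)),
        recall=float(curve.recall_at(a0)),
        subset_size=curve.subset_size_at(a0),
    )


def export_curve_tsv(curve: RPCurve, path) -> None:
    curve.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def plot_curves(curves: dict[str, RPCurve], path, smoothed: bool = True) -> None:
    """Recall (y) vs precision (x), one line per model."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for name, c in curves.items():
        x = c.p_smooth if smoothed else c.p_raw
        y = c.r_smooth if smoothed else c.r_raw
        ax.plot(x, y, marker=".", label=name)
    ax.set_xlabel("Precision")
    ax.set_ylabel("Recall")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
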