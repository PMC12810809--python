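"""ROC analysis for predicting nodal metastasis from a continuous depth score.

The curve is built by sweeping the decision rule "positive if score >= t"
over the distinct observed scores in descending order, so there is one
curve point per distinct threshold plus the (0, 0) anchor.  The AUC is the
Mann-Whitney probability that a random positive outscores a random
negative (ties half-credited), which equals the trapezoidal area under
that curve; both are computed and cross-checked.

Cutoffs are reported at the midpoint between the two adjacent distinct
observed scores that the optimal rule separates (matching the convention
of common statistical packages, which is how cutoffs like 9.5 mm arise
from data recorded at 0.1 mm resolution), or at the observed score itself
when it is the smallest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Literal, Tuple

import numpy as np

__all__ = ["RocReport", "roc_curve", "auc", "youden_cutoff", "roc_report"]

CutoffCriterion = Literal["youden", "closest_topleft"]


@dataclass(frozen=True)
class RocReport:
    """ROC curve, AUC and optimal operating point for one score."""

    n_pos: int
    n_neg: int
    auc: float
    #: (fpr, tpr, threshold) triples from (0,0) [threshold inf] to (1,1).
    curve: List[Tuple[float, float, float]]
    optimal_cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    youden_j: float
    criterion: CutoffCriterion = "youden"

    def to_dict(self, rounded_decimals: int = 3) -> dict:
        return {
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "auc": self.auc,
            "optimal_cutoff": self.optimal_cutoff,
            "sens_at_cutoff": self.sens_at_cutoff,
            "spec_at_cutoff": self.spec_at_cutoff,
            "youden_j": self.youden_j,
            "criterion": self.criterion,
            "curve": [list(p) for p in self.curve],
            "rounded": {
                k: round(getattr(self, k), rounded_decimals)
                for k in ("auc", "optimal_cutoff", "sens_at_cutoff", "spec_at_cutoff", "youden_j")
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def curve_array(self) -> np.ndarray:
        return np.asarray(self.curve, dtype=float)


def _validate(scores, labels) -> Tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-d vectors of equal length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    labels = labels.astype(int)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    if labels.min() == labels.max():
        raise ValueError("both outcome classes must be present")
    return scores, labels


def roc_curve(scores, labels) -> List[Tuple[float, float, float]]:
    """(fpr, tpr, threshold) triples for the rule score >= threshold.

    Starts at (0, 0) with threshold +inf and ends at (1, 1) at the
    minimum observed score; tied scores contribute a single point.
    Higher scores must indicate the positive class.
    """
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos

    thresholds = np.unique(scores)[::-1]
    points = [(0.0, 0.0, float("inf"))]
    for t in thresholds:
        called_pos = scores >= t
        tpr = float((called_pos & (labels == 1)).sum() / n_pos)
        fpr = float((called_pos & (labels == 0)).sum() / n_neg)
        points.append((fpr, tpr, float(t)))
    return points


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(random positive score > random negative) with
    half credit for ties, averaged over all positive-negative pairs.
    """
    scores, labels = _validate(scores, labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return float((gt + 0.5 * eq) / (pos.size * neg.size))


def trapezoidal_auc(curve: List[Tuple[float, float, float]]) -> float:
    """Area under a (fpr, tpr) polyline by the trapezoid rule."""
    arr = np.asarray(curve, dtype=float)
    return float(np.trapezoid(arr[:, 1], arr[:, 0]))


def _midpoint_cutoff(threshold: float, scores: np.ndarray) -> float:
    """Place the reported cutoff between the separated observed scores."""
    if not np.isfinite(threshold):
        return float(np.max(scores))  # degenerate: nothing called positive
    below = scores[scores < threshold]
    if below.size == 0:
        return float(threshold)
    return float((threshold + below.max()) / 2.0)


def youden_cutoff(
    scores, labels, criterion: CutoffCriterion = "youden"
) -> Tuple[float, float, float]:
    """Optimal cutoff (cutoff, sensitivity, specificity).

    ``youden`` maximises sensitivity + specificity - 1;
    ``closest_topleft`` minimises the Euclidean distance to the ideal
    (0, 1) corner.  Ties are broken toward the higher threshold (fewer
    test positives).
    """
    scores_arr, _ = _validate(scores, labels)
    curve = roc_curve(scores, labels)
    best = None
    for fpr, tpr, t in curve[1:]:  # skip the empty-positive anchor
        if criterion == "youden":
            value = tpr - fpr
        elif criterion == "closest_topleft":
            value = -np.hypot(fpr, 1.0 - tpr)
        else:
            raise ValueError(f"unknown cutoff criterion {criterion!r}")
        # strict > keeps the earlier (higher-threshold) point on ties
        if best is None or value > best[0]:
            best = (value, fpr, tpr, t)
    _, fpr, tpr, t = best
    return _midpoint_cutoff(t, scores_arr), tpr, 1.0 - fpr


def roc_report(scores, labels, criterion: CutoffCriterion = "youden") -> RocReport:
    """Full ROC analysis of one score: curve, AUC, optimal cutoff.

    Internally asserts the Mann-Whitney AUC equals the trapezoidal area
    under the constructed curve.
    """
    scores_arr, labels_arr = _validate(scores, labels)
    curve = roc_curve(scores_arr, labels_arr)
    a = auc(scores_arr, labels_arr)
    a_trap = trapezoidal_auc(curve)
    if abs(a - a_trap) > 1e-12:
        raise AssertionError(
            f"AUC mismatch: Mann-Whitney {a!r} vs trapezoidal {a_trap!r}"
        )
    cutoff, sens, spec = youden_cutoff(scores_arr, labels_arr, criterion)
    return RocReport(
        n_pos=int(labels_arr.sum()),
        n_neg=int(labels_arr.size - labels_arr.sum()),
        auc=a,
        curve=curve,
        optimal_cutoff=cutoff,
        sens_at_cutoff=sens,
        spec_at_cutoff=spec,
        youden_j=sens + spec - 1.0,
        criterion=criterion,
    )
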