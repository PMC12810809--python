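"""Composite us/mrDOI biomarker: switching rule and threshold grid search.

The composite depth score uses the ultrasound measurement for shallow
tumours and switches to MRI above a threshold::

    us/mrDOI(t) = usDOI   if usDOI <= t
                  mrDOI   if usDOI >  t

The switching threshold is chosen by a data-driven grid search: candidate
thresholds are the deciles (10th-90th percentiles by default) of the
observed usDOI distribution in the complete-case subset; for each
candidate a univariable logistic regression of nodal metastasis on the
composite score is fitted and the ROC AUC computed; the threshold with
the maximal AUC wins, with ties broken toward the smallest threshold
(keeping the better-validated ultrasound regime for more patients).

The AUC used for selection is computed from the composite score itself:
it is identical to the AUC of the fitted logistic probability whenever
the fitted slope is positive (the logit is monotone), and unlike the fit
it cannot fail to converge.  The equivalence is asserted on every grid
cell with a positive slope; a negative fitted slope raises a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .roc import auc as roc_auc

__all__ = [
    "SeparationWarning",
    "GridSearchResult",
    "compose_doi",
    "candidate_thresholds",
    "fit_logistic",
    "grid_search",
    "complete_cases",
]

DEFAULT_PERCENTILES = (10, 20, 30, 40, 50, 60, 70, 80, 90)


class SeparationWarning(UserWarning):
    """Raised when a logistic fit encounters (quasi-)complete separation."""


@dataclass(frozen=True)
class GridSearchResult:
    """Outcome of the switching-threshold grid search."""

    candidate_thresholds: List[float]
    auc_per_threshold: List[float]
    best_threshold: float
    best_auc: float
    n_complete: int
    logit_coefficients_at_best: Tuple[float, float]
    n_switched_per_threshold: List[int] = field(default_factory=list)
    percentile_levels: List[int] = field(default_factory=list)

    def to_dict(self, rounded_decimals: int = 3) -> dict:
        return {
            "candidate_thresholds": self.candidate_thresholds,
            "auc_per_threshold": self.auc_per_threshold,
            "best_threshold": self.best_threshold,
            "best_auc": self.best_auc,
            "n_complete": self.n_complete,
            "logit_coefficients_at_best": list(self.logit_coefficients_at_best),
            "n_switched_per_threshold": self.n_switched_per_threshold,
            "percentile_levels": self.percentile_levels,
            "rounded": {
                "best_threshold": round(self.best_threshold, rounded_decimals),
                "best_auc": round(self.best_auc, rounded_decimals),
                "auc_per_threshold": [round(a, rounded_decimals) for a in self.auc_per_threshold],
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_frame(self) -> pd.DataFrame:
        """Per-threshold table (threshold_mm, auc, n_switched_to_mri)."""
        return pd.DataFrame(
            {
                "threshold_mm": self.candidate_thresholds,
                "auc": self.auc_per_threshold,
                "n_switched_to_mri": self.n_switched_per_threshold,
            }
        )


def compose_doi(us_doi, mr_doi, threshold: float):
    """The switching rule: usDOI where usDOI <= threshold, else mrDOI.

    The boundary stays with ultrasound (switching only for usDOI strictly
    above the threshold).  Vectorised; rejects missing values, since the
    composite is defined only on complete usDOI/mrDOI pairs.
    """
    us = np.asarray(us_doi, dtype=float)
    mr = np.asarray(mr_doi, dtype=float)
    if us.shape != mr.shape:
        raise ValueError("us_doi and mr_doi must have matching shapes")
    if not (np.isfinite(us).all() and np.isfinite(mr).all()):
        raise ValueError("composite DOI requires both measurements present and finite")
    out = np.where(us > threshold, mr, us)
    return float(out) if out.ndim == 0 else out


def candidate_thresholds(
    us_values,
    percentiles: Sequence[int] = DEFAULT_PERCENTILES,
    method: str = "linear",
) -> np.ndarray:
    """Sample percentiles of the usDOI distribution, deduplicated, sorted.

    With the default decile levels and continuous data this yields exactly
    nine candidates.  ``method`` is any percentile interpolation convention
    accepted by :func:`numpy.percentile` (the published grid cannot
    adjudicate the convention, so it is configurable; linear interpolation
    between order statistics is the default).
    """
    us = np.asarray(us_values, dtype=float)
    us = us[~np.isnan(us)]
    if us.size == 0:
        raise ValueError("candidate_thresholds: no usDOI values")
    levels = np.asarray(list(percentiles), dtype=float)
    if levels.size == 0 or (levels < 1).any() or (levels > 99).any():
        raise ValueError("percentile levels must lie within [1, 99]")
    qs = np.percentile(us, levels, method=method)
    return np.unique(qs)


def fit_logistic(
    x, labels, max_iter: int = 100, tol: float = 1e-8
) -> Tuple[float, float, bool]:
    """Univariable logistic regression by iteratively reweighted least squares.

    Returns (intercept, slope, converged).  Convergence is declared when
    the largest absolute coefficient update falls below ``tol`` (default
    1e-8) within ``max_iter`` iterations.  Under complete separation the
    likelihood is monotone and the coefficients diverge; the last iterate
    is returned with ``converged=False`` and a :class:`SeparationWarning`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and labels must be 1-d vectors of equal length")
    if x.size < 4:
        raise ValueError(f"need at least 4 observations, got {x.size}")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be binary (0/1)")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")

    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        z = eta + (y - mu) / w
        XtW = X.T * w
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            break
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol:
            converged = True
            break

    separated = bool(
        np.min(x[y == 1]) > np.max(x[y == 0]) or np.max(x[y == 1]) < np.min(x[y == 0])
    )
    if not converged or separated:
        converged = False
        warnings.warn(
            "logistic fit did not converge (monotone likelihood / complete "
            "separation suspected); returning last iterate",
            SeparationWarning,
            stacklevel=2,
        )
    return float(beta[0]), float(beta[1]), converged


def complete_cases(cohort: pd.DataFrame) -> pd.DataFrame:
    """Records with usDOI, mrDOI, pDOI and the CLNM label all present."""
    mask = (
        cohort["us_doi_mm"].notna()
        & cohort["mr_doi_mm"].notna()
        & cohort["p_doi_mm"].notna()
        & cohort["clnm"].notna()
    )
    return cohort[mask]


def grid_search(
    cohort: pd.DataFrame,
    percentiles: Sequence[int] = DEFAULT_PERCENTILES,
    percentile_method: str = "linear",
) -> GridSearchResult:
    """Decile grid search for the optimal US-to-MRI switching threshold.

    Restricted to the complete-case subset.  For every candidate
    threshold the composite score is built, a univariable logistic model
    of CLNM on the composite is fitted (coefficients retained), and the
    AUC of the composite score computed.  The AUC-maximising threshold is
    returned; ties go to the smallest threshold.
    """
    cc = complete_cases(cohort)
    n_complete = len(cc)
    if n_complete < 4:
        raise ValueError(
            f"grid search requires >= 4 complete cases (usDOI, mrDOI, CLNM); got n_complete={n_complete}"
        )
    labels = cc["clnm"].to_numpy(dtype=int)
    if labels.min() == labels.max():
        raise ValueError("grid search requires both CLNM classes among complete cases")
    us = cc["us_doi_mm"].to_numpy(dtype=float)
    mr = cc["mr_doi_mm"].to_numpy(dtype=float)

    grid = candidate_thresholds(us, percentiles, method=percentile_method)
    aucs: List[float] = []
    n_switched: List[int] = []
    coefs: List[Tuple[float, float]] = []
    for t in grid:
        comp = compose_doi(us, mr, float(t))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SeparationWarning)
            b0, b1, _ = fit_logistic(comp, labels)
        a = roc_auc(comp, labels)
        if b1 > 0:
            # monotone-logit cross-check: fitted probability ranks = score ranks
            a_fit = roc_auc(1.0 / (1.0 + np.exp(-(b0 + b1 * comp))), labels)
            if abs(a - a_fit) > 1e-12:
                raise AssertionError("composite AUC differs from fitted-probability AUC")
        elif b1 < 0:
            warnings.warn(
                f"negative logistic slope at threshold {t:.3g} mm: composite AUC "
                "and fitted-probability AUC rank cases in opposite order",
                UserWarning,
                stacklevel=2,
            )
        aucs.append(float(a))
        n_switched.append(int((us > t).sum()))
        coefs.append((b0, b1))

    best_idx = int(np.argmax(aucs))  # argmax takes the first = smallest threshold
    return GridSearchResult(
        candidate_thresholds=[float(t) for t in grid],
        auc_per_threshold=aucs,
        best_threshold=float(grid[best_idx]),
        best_auc=float(aucs[best_idx]),
        n_complete=n_complete,
        logit_coefficients_at_best=coefs[best_idx],
        n_switched_per_threshold=n_switched,
        percentile_levels=[int(p) for p in percentiles],
    )
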