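"""Correlation and Bland-Altman agreement between an imaging DOI and pathology.

Sign convention, fixed throughout: differences are *imaging minus
pathology*, so a positive bias means the imaging modality overestimates
depth.  Limits of agreement use the conventional 1.96 multiplier on the
sample SD (n-1 denominator), not a small-sample t quantile.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "AgreementReport",
    "pearson_with_test",
    "linear_fit",
    "bland_altman",
    "proportional_bias_test",
]

LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class AgreementReport:
    """Agreement of one imaging modality with the pathology reference.

    ``bias`` is the mean imaging-minus-pathology difference (mm),
    ``loa_low``/``loa_high`` the 95% limits of agreement
    (bias -/+ 1.96 x SD of differences), and ``prop_bias_slope`` the OLS
    slope of the differences on the pairwise means (a significantly
    negative slope operationalises depth-dependent underestimation).
    Proportional-bias fields are None when fewer than 3 pairs are
    available.
    """

    n_pairs: int
    pearson_r: float
    r_p_value: float
    slope: float
    intercept: float
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    prop_bias_slope: Optional[float]
    prop_bias_p: Optional[float]

    def to_dict(self, rounded_decimals: int = 2) -> dict:
        d = asdict(self)
        d["rounded"] = {
            k: (None if v is None else round(v, rounded_decimals))
            for k, v in asdict(self).items()
            if k != "n_pairs"
        }
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _as_pair(x, y, min_n: int) -> Tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"inputs must be 1-d vectors of equal length, got {x.shape} and {y.shape}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("inputs must not contain missing values; subset complete pairs first")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {x.size}")
    return x, y


def pearson_with_test(x, y) -> Tuple[float, float]:
    """Sample product-moment correlation with its two-sided t-test p-value
    (n - 2 degrees of freedom).  Requires n >= 3 and non-constant inputs.
    """
    x, y = _as_pair(x, y, 3)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def linear_fit(x, y) -> Tuple[float, float, float]:
    """Ordinary least squares of y on x: (slope, intercept, residual SD).

    Residual SD uses n - 2 denominator (two estimated coefficients).
    """
    x, y = _as_pair(x, y, 3)
    if np.ptp(x) == 0:
        raise ValueError("linear fit undefined for constant x")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    rsd = math.sqrt(float(resid @ resid) / (x.size - 2))
    return float(res.slope), float(res.intercept), rsd


def proportional_bias_test(measure, reference) -> Tuple[float, float]:
    """Regress differences (measure - reference) on pairwise means.

    Returns the OLS slope and its two-sided t-test p-value.  A clearly
    negative slope indicates the measurement error grows more negative
    with magnitude, i.e. underestimation of deep lesions.
    """
    measure, reference = _as_pair(measure, reference, 3)
    diffs = measure - reference
    means = (measure + reference) / 2.0
    if np.ptp(means) == 0:
        raise ValueError("proportional-bias test undefined for constant pairwise means")
    res = stats.linregress(means, diffs)
    return float(res.slope), float(res.pvalue)


def bland_altman(measure, reference) -> AgreementReport:
    """Bland-Altman agreement of ``measure`` against ``reference``.

    Differences are measure - reference; bias is their mean, sd_diff the
    sample SD (n-1), limits of agreement bias +/- 1.96 x sd_diff.  Also
    reports the Pearson correlation and OLS fit of measure on reference,
    and the proportional-bias regression of differences on pairwise means
    (omitted for n < 3 pairs).
    """
    measure, reference = _as_pair(measure, reference, 2)
    n = measure.size
    diffs = measure - reference
    bias = float(np.mean(diffs))
    sd_diff = float(np.std(diffs, ddof=1))

    if np.ptp(measure) > 0 and np.ptp(reference) > 0 and n >= 3:
        r, r_p = pearson_with_test(reference, measure)
    else:
        r, r_p = float("nan"), float("nan")
    if np.ptp(reference) > 0 and n >= 3:
        slope, intercept, _ = linear_fit(reference, measure)
    else:
        slope, intercept = float("nan"), float("nan")

    prop_slope: Optional[float] = None
    prop_p: Optional[float] = None
    if n >= 3:
        means = (measure + reference) / 2.0
        if np.ptp(means) > 0:
            prop_slope, prop_p = proportional_bias_test(measure, reference)

    return AgreementReport(
        n_pairs=n,
        pearson_r=r,
        r_p_value=r_p,
        slope=slope,
        intercept=intercept,
        bias=bias,
        sd_diff=sd_diff,
        loa_low=bias - LOA_MULTIPLIER * sd_diff,
        loa_high=bias + LOA_MULTIPLIER * sd_diff,
        prop_bias_slope=prop_slope,
        prop_bias_p=prop_p,
    )
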