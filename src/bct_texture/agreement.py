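"""Reader-study statistics: agreement, kappa, ICC, feature stability.

Two radiologists grading the same examinations produce a K x K confusion
matrix against a reference reader; this module derives the standard
reliability summaries from it — raw percent agreement, Cohen's
chance-corrected kappa with its Landis–Koch verbal band, the two-way
random-effects absolute-agreement intraclass correlation ICC(2,1) for
ordinal/continuous ratings, and the per-feature inter-reader coefficient
of variation that quantifies how sensitive each texture feature is to
who drew the ROI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .classifier import ConfusionMatrix

__all__ = [
    "AgreementResult",
    "KappaResult",
    "IccResult",
    "percent_agreement",
    "cohens_kappa",
    "landis_koch_label",
    "icc_absolute",
    "feature_cv",
    "interreader_feature_cv",
]


@dataclass
class AgreementResult:
    percent: float  # raw
    percent_rounded: int  # nearest integer, for reporting


@dataclass
class KappaResult:
    kappa: float
    label: str
    p_observed: float
    p_expected: float


@dataclass
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    variant: str = "ICC(2,1) absolute agreement"


def percent_agreement(cm: ConfusionMatrix) -> AgreementResult:
    """Fraction of items on the diagonal, in percent."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    pct = 100.0 * np.trace(cm.counts) / cm.total
    return AgreementResult(percent=float(pct), percent_rounded=int(round(pct)))


def landis_koch_label(kappa: float) -> str:
    if np.isnan(kappa):
        return "undefined"
    if kappa < 0:
        return "poor"
    bands = [(0.20, "slight"), (0.40, "fair"), (0.60, "moderate"), (0.80, "substantial")]
    for upper, name in bands:
        if kappa <= upper:
            return name
    return "almost perfect"


def cohens_kappa(cm: ConfusionMatrix) -> KappaResult:
    """Chance-corrected agreement ``(p_o - p_e) / (1 - p_e)``.

    ``p_e`` comes from the product of the marginal distributions.  When
    both raters use a single category, ``p_e = 1`` and kappa is
    undefined; it is returned as NaN with label ``undefined``.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    n = cm.total
    p_o = float(np.trace(cm.counts)) / n
    rows = cm.counts.sum(axis=1) / n
    cols = cm.counts.sum(axis=0) / n
    p_e = float(rows @ cols)
    if p_e >= 1.0 - 1e-12:
        return KappaResult(float("nan"), "undefined", p_o, p_e)
    kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(float(kappa), landis_koch_label(kappa), p_o, p_e)


def icc_absolute(ratings: pd.DataFrame, alpha: float = 0.05) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is items x raters with no missing cells (ordinal grades
    should be coded numerically).  With ``n`` items, ``k`` raters and the
    two-way mean squares MSR (rows/items), MSC (columns/raters) and MSE,

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    The confidence interval is the standard F-based one (Satterthwaite
    degrees of freedom for the rater term); when the residual mean square
    is exactly zero the interval degenerates to the point estimate.
    """
    from scipy.stats import f as f_dist

    r = ratings.to_numpy(float)
    n, k = r.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 items and 2 raters")
    if np.isnan(r).any():
        raise ValueError("missing cells are not supported")
    if np.ptp(r.mean(axis=1)) == 0:
        raise ValueError("zero between-item variance: ICC undefined")
    grand = r.mean()
    msr = k * float(((r.mean(axis=1) - grand) ** 2).sum()) / (n - 1)
    msc = n * float(((r.mean(axis=0) - grand) ** 2).sum()) / (k - 1)
    ss_total = float(((r - grand) ** 2).sum())
    mse = max(0.0, ss_total - (n - 1) * msr - (k - 1) * msc) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("zero between-item variance: ICC undefined")
    icc = (msr - mse) / denom
    if mse == 0:
        return IccResult(icc=icc, ci_low=icc, ci_high=icc)
    fj = msc / mse
    vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
    v = vn / vd
    f_u = f_dist.ppf(1 - alpha / 2, n - 1, v)
    f_l = f_dist.ppf(1 - alpha / 2, v, n - 1)
    ci_low = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    ci_high = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    return IccResult(icc=float(icc), ci_low=float(ci_low), ci_high=float(ci_high))


def feature_cv(values: pd.DataFrame) -> tuple[float, pd.Series, list]:
    """Inter-reader coefficient of variation for one feature.

    ``values`` is items x readers.  Per item,
    ``CV = 100 * sd(readers) / mean(readers)`` (sample sd, ddof=1); the
    sign of the mean is carried, so features that average negative (e.g.
    skewness in dense breasts) report a negative CV.  Items with zero
    mean are excluded and returned in the third element.  The headline
    number is the mean per-item CV.
    """
    v = values.to_numpy(float)
    if v.shape[1] < 2:
        raise ValueError("need at least 2 readers")
    means = v.mean(axis=1)
    sds = v.std(axis=1, ddof=1)
    ok = means != 0
    excluded = list(values.index[~ok])
    if not ok.any():
        raise ValueError("all items have zero mean: CV undefined")
    cv_items = pd.Series(100.0 * sds[ok] / means[ok], index=values.index[ok], name="cv_percent")
    return float(cv_items.mean()), cv_items, excluded


def interreader_feature_cv(per_reader_feature_values: Mapping[str, pd.DataFrame]) -> pd.Series:
    """Mean per-item CV for each feature; input maps feature -> items x readers."""
    out = {}
    for feature, values in per_reader_feature_values.items():
        out[feature], _, _ = feature_cv(values)
    return pd.Series(out, name="cv_percent")
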