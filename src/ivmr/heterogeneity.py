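"""Pleiotropy and heterogeneity diagnostics.

Cochran's Q measures dispersion of the per-variant Wald ratios around the
fixed-effect IVW estimate; I² = max(0, (Q − df)/Q) expresses the share of
that dispersion beyond sampling error, with a test-based confidence
interval on H = sqrt(Q/df) after Higgins & Thompson. The MR-Egger
intercept test reports the intercept of the Egger regression, whose
departure from zero indicates average directional pleiotropy.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

from .estimators import MREstimate, Z95, egger
from .exceptions import InsufficientInstrumentsError
from .summary_data import HarmonizedSet

__all__ = ["HeterogeneityResult", "EggerInterceptTest", "cochran_q", "egger_intercept_test"]


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its chi-square p-value and I² (percent) with CI."""

    q: float
    df: int
    pvalue: float
    i2: float
    i2_ci_low: float
    i2_ci_high: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class EggerInterceptTest:
    """The Egger intercept with a flag for directional pleiotropy at ``alpha``."""

    estimate: MREstimate
    alpha: float
    directional_pleiotropy: bool

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate.to_dict(),
            "alpha": self.alpha,
            "directional_pleiotropy": self.directional_pleiotropy,
        }


def _i2_from_h(h: float) -> float:
    """I² (percent) implied by H, truncated at 0."""
    return max(0.0, (h * h - 1.0) / (h * h) * 100.0) if h > 0 else 0.0


def cochran_q(data: HarmonizedSet) -> HeterogeneityResult:
    """Cochran's Q heterogeneity test on the Wald-ratio scale.

    Ratios r_j = beta_out/beta_exp with weights w_j = (beta_exp/se_out)²
    are compared to the fixed-effect IVW estimate:
    Q = Σ w_j (r_j − β_IVW)², df = k − 1, p from the upper tail of
    chi-square(df). The Q computed this way is algebraically identical to
    the weighted residual sum of squares of the through-origin regression.

    The I² confidence interval uses the test-based method on
    H = sqrt(Q/df): a normal interval for ln H with
    se(ln H) = (ln Q − ln df) / (2(sqrt(2Q) − sqrt(2k−3))) when Q > k,
    else sqrt((1/(2(k−2)))(1 − 1/(3(k−2)²))), back-transformed and
    truncated to [0, 100].
    """
    k = data.k
    if k < 2:
        raise InsufficientInstrumentsError(f"Cochran's Q requires k >= 2 (got {k})")
    bx = np.array([v.beta_exp for v in data.variants])
    by = np.array([v.beta_out for v in data.variants])
    sy = np.array([v.se_out for v in data.variants])
    r = by / bx
    w = (bx / sy) ** 2
    beta_fixed = float(np.sum(w * r) / np.sum(w))
    q = float(np.sum(w * (r - beta_fixed) ** 2))
    df = k - 1
    pvalue = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q * 100.0) if q > 0 else 0.0

    if q > 0:
        h = max(np.sqrt(q / df), 1e-12)
        if q > k:
            se_ln_h = 0.5 * (np.log(q) - np.log(df)) / (
                np.sqrt(2.0 * q) - np.sqrt(2.0 * k - 3.0)
            )
        elif k > 2:
            se_ln_h = np.sqrt((1.0 / (2.0 * (k - 2))) * (1.0 - 1.0 / (3.0 * (k - 2) ** 2)))
        else:
            se_ln_h = None  # two studies, small Q: interval is uninformative
        if se_ln_h is None:
            i2_lo, i2_hi = 0.0, 100.0
        else:
            ln_h = np.log(h)
            h_low = float(np.exp(ln_h - Z95 * se_ln_h))
            h_high = float(np.exp(ln_h + Z95 * se_ln_h))
            i2_lo, i2_hi = _i2_from_h(h_low), _i2_from_h(h_high)
    else:
        i2_lo = i2_hi = 0.0

    return HeterogeneityResult(
        q=q, df=df, pvalue=pvalue, i2=i2,
        i2_ci_low=min(i2_lo, 100.0), i2_ci_high=min(i2_hi, 100.0),
    )


def egger_intercept_test(data: HarmonizedSet, alpha: float = 0.05) -> EggerInterceptTest:
    """MR-Egger intercept test for average directional pleiotropy.

    Returns the intercept component of :func:`~ivmr.estimators.egger` and
    flags directional pleiotropy when its two-sided p-value falls below
    ``alpha`` (0.05 by default).
    """
    intercept = egger(data).intercept
    return EggerInterceptTest(
        estimate=intercept,
        alpha=alpha,
        directional_pleiotropy=intercept.pvalue < alpha,
    )
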