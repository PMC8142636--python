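"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators operate on a :class:`~ivmr.summary_data.HarmonizedSet` and
return :class:`MREstimate` records. Notation: for variant *j*,
``beta_exp`` (γ̂_j) is the instrument–exposure effect, ``beta_out`` (Γ̂_j)
the instrument–outcome effect, and the Wald ratio Γ̂_j / γ̂_j is the
single-instrument causal estimate.

* **IVW** — weighted regression of Γ̂ on γ̂ through the origin with weights
  1/se_out²; by default a multiplicative random-effects model whose SE is
  the fixed-effect SE inflated by max(1, sqrt(Q/(k−1))).
* **MR-Egger** — the same regression with a free intercept; the slope is
  the causal estimate under the InSIDE assumption and the intercept
  measures average directional pleiotropy. SEs inflated by
  max(1, sqrt(Q_egger/(k−2))).
* **Weighted median** — the interpolated median of the Wald ratios under
  weights (γ̂/se_out)², consistent when valid instruments carry more than
  half the weight; SE by parametric bootstrap.

Confidence intervals and p-values use standard-normal quantiles
throughout (the MR-PRESSO module applies a Student-t reference instead;
see :mod:`ivmr.mr_presso`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateWeightsError,
    InsufficientInstrumentsError,
    UndefinedRatioError,
)
from .summary_data import HarmonizedSet, HarmonizedVariant

__all__ = [
    "MREstimate",
    "EggerResult",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "interpolated_weighted_median",
    "estimates_to_frame",
]

#: two-sided 95% standard-normal quantile
Z95 = float(stats.norm.ppf(0.975))

_TINY_P = 5e-324  # smallest positive double; keeps p in (0, 1]


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate with its uncertainty.

    ``inflation`` is the multiplicative dispersion factor already applied
    to ``se`` (1 when no overdispersion adjustment was made); ``ref_dist``
    names the reference distribution of the p-value ("normal" or "t", with
    ``df`` set for the latter).
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    k: int
    inflation: float = 1.0
    ref_dist: str = "normal"
    df: int | None = None

    def __post_init__(self):
        if not self.se > 0:
            raise ValueError(f"{self.method}: se must be positive")
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError(f"{self.method}: beta outside its CI")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"{self.method}: p-value outside (0, 1]")
        if self.inflation < 1.0:
            raise ValueError(f"{self.method}: inflation below 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class EggerResult(NamedTuple):
    slope: MREstimate
    intercept: MREstimate


def _arrays(data: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    bx = np.array([v.beta_exp for v in data.variants], dtype=float)
    sx = np.array([v.se_exp for v in data.variants], dtype=float)
    by = np.array([v.beta_out for v in data.variants], dtype=float)
    sy = np.array([v.se_out for v in data.variants], dtype=float)
    return bx, sx, by, sy


def _normal_p(z: float) -> float:
    return max(2.0 * float(stats.norm.sf(abs(z))), _TINY_P)


def wald_ratio(v: HarmonizedVariant) -> MREstimate:
    """Single-instrument ratio estimate Γ̂/γ̂ with first-order delta-method SE.

    The exposure measurement error is ignored (SE = se_out / |beta_exp|),
    the convention under which the multi-instrument estimators below are
    weighted averages of these ratios.
    """
    if v.beta_exp == 0:
        raise UndefinedRatioError(f"{v.snp_id}: exposure effect is zero")
    beta = v.beta_out / v.beta_exp
    se = v.se_out / abs(v.beta_exp)
    return MREstimate(
        method="wald_ratio",
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pvalue=_normal_p(beta / se),
        k=1,
    )


def ivw(data: HarmonizedSet, model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance weighted estimate.

    Weighted least squares of ``beta_out`` on ``beta_exp`` through the
    origin with weights 1/se_out². Under ``model="fixed"`` the SE is the
    classical 1/sqrt(Σ beta_exp²/se_out²); under the default
    ``"multiplicative_random"`` it is inflated by max(1, sqrt(Q/(k−1)))
    where Q is the weighted residual sum of squares, so heterogeneity
    widens — never narrows — the interval.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    k = data.k
    if k == 0:
        raise InsufficientInstrumentsError("IVW requires at least one instrument")
    if model == "multiplicative_random" and k < 2:
        raise InsufficientInstrumentsError(
            "multiplicative random-effects IVW requires at least 2 instruments"
        )
    bx, _, by, sy = _arrays(data)
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx**2))
    if sxx <= 0 or not np.isfinite(sxx):
        raise DegenerateWeightsError("total IVW weight is zero or non-finite")
    beta = float(np.sum(w * bx * by)) / sxx
    se_fixed = 1.0 / np.sqrt(sxx)
    inflation = 1.0
    if model == "multiplicative_random":
        q = float(np.sum(w * (by - beta * bx) ** 2))
        inflation = max(1.0, np.sqrt(q / (k - 1)))
    se = se_fixed * inflation
    return MREstimate(
        method="ivw",
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pvalue=_normal_p(beta / se),
        k=k,
        inflation=inflation,
    )


def egger(data: HarmonizedSet) -> EggerResult:
    """MR-Egger regression: slope (causal estimate) and intercept (pleiotropy).

    Weighted least squares of ``beta_out`` on ``beta_exp`` *with* an
    intercept, weights 1/se_out². Standard errors come from the WLS
    information matrix, both inflated by max(1, sqrt(Q_egger/(k−2))).
    Requires harmonized data (all ``beta_exp`` positive) for the intercept
    to carry its directional-pleiotropy interpretation.
    """
    k = data.k
    if k < 3:
        raise InsufficientInstrumentsError(f"MR-Egger requires k >= 3 (got {k})")
    bx, _, by, sy = _arrays(data)
    w = 1.0 / sy**2
    x_design = np.column_stack([np.ones(k), bx])
    xtwx = x_design.T @ (w[:, None] * x_design)
    coef = np.linalg.solve(xtwx, x_design.T @ (w * by))
    resid = by - x_design @ coef
    q_egger = float(np.sum(w * resid**2))
    inflation = max(1.0, np.sqrt(q_egger / (k - 2)))
    cov = np.linalg.inv(xtwx)
    ses = np.sqrt(np.diag(cov)) * inflation

    def _estimate(method: str, b: float, s: float) -> MREstimate:
        return MREstimate(
            method=method,
            beta=b,
            se=s,
            ci_low=b - Z95 * s,
            ci_high=b + Z95 * s,
            pvalue=_normal_p(b / s),
            k=k,
            inflation=inflation,
        )

    return EggerResult(
        slope=_estimate("egger_slope", float(coef[1]), float(ses[1])),
        intercept=_estimate("egger_intercept", float(coef[0]), float(ses[0])),
    )


def interpolated_weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by linear interpolation of the cumulative weight.

    Values are sorted; the standardized cumulative weight of the j-th order
    statistic is p_j = (S_j − w_j/2) / S_total with S_j the running weight
    sum, and the median is the interpolation of value against p at p = 0.5.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    total = float(np.sum(weights))
    if not (total > 0 and np.isfinite(total)):
        raise DegenerateWeightsError("total weight is zero or non-finite")
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    p = (np.cumsum(w) - w / 2.0) / total
    return float(np.interp(0.5, p, v))


def weighted_median(
    data: HarmonizedSet, n_boot: int = 1000, seed: int | None = None
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Ratios r_j = beta_out/beta_exp receive weights (beta_exp/se_out)²; the
    point estimate is the interpolated weighted median. The SE is the
    standard deviation of ``n_boot`` replicate estimates obtained by
    redrawing beta_exp and beta_out from normal(beta, se) per variant
    (weights recomputed per replicate); CI and p use the normal reference.
    """
    k = data.k
    if k < 3:
        raise InsufficientInstrumentsError(f"weighted median requires k >= 3 (got {k})")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    bx, sx, by, sy = _arrays(data)
    ratios = by / bx
    weights = (bx / sy) ** 2
    beta = interpolated_weighted_median(ratios, weights)

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_boot, k))
    by_star = rng.normal(by, sy, size=(n_boot, k))
    reps = np.empty(n_boot)
    for i in range(n_boot):
        reps[i] = interpolated_weighted_median(
            by_star[i] / bx_star[i], (bx_star[i] / sy) ** 2
        )
    se = float(np.std(reps, ddof=1)) if n_boot > 1 else 0.0
    if se == 0:  # all replicates identical (noiseless data) or a single replicate
        se = _TINY_P
        pvalue = _TINY_P if beta != 0 else 1.0
        return MREstimate(
            method="weighted_median", beta=beta, se=se, ci_low=beta, ci_high=beta,
            pvalue=pvalue, k=k,
        )
    return MREstimate(
        method="weighted_median",
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pvalue=_normal_p(beta / se),
        k=k,
    )


def estimates_to_frame(estimates, outcome: str | None = None):
    """Tabulate estimates: one row per method, optionally labelled by outcome."""
    import pandas as pd

    rows = []
    for est in estimates:
        d = est.to_dict()
        if outcome is not None:
            d = {"outcome": outcome, **d}
        rows.append(d)
    return pd.DataFrame(rows)
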