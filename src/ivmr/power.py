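"""Instrument strength and statistical power for a binary outcome.

The variance in the exposure explained by instrument *i* is computed from
its F-statistic, R²_i = F_i / (F_i + n_i − 2) with F_i = (β_i/se_i)²; the
instrument set's total R² is the sum over the (independent) instruments.

Power for a binary outcome uses the standard non-centrality approximation
for an instrumental-variable log-odds estimate: with case fraction
K = n_cases/N the attenuated effect is b = K·(OR/(1 + K·(OR − 1)) − 1),
its variance v = (K(1 − K) − b²)/(N·R²), and power is the upper-tail
probability of a noncentral chi-square(1, b²/v) beyond the central
chi-square critical value at 1 − alpha. ``detectable_or`` inverts this
relationship by bisection to find the odds ratio detectable at a target
power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import BracketError, ConfigurationError
from .summary_data import VariantAssociation

__all__ = [
    "PowerInput",
    "VarianceExplained",
    "POWER_PRESETS",
    "variance_explained",
    "binary_power",
    "detectable_or",
]

#: named case/control configurations of the Parkinson's disease outcome GWAS:
#: the full meta-analysis counts and the publicly available analysis subset
POWER_PRESETS: dict[str, dict[str, int]] = {
    "pd_full_meta": {"n_total": 1_474_097, "n_cases": 56_306},
    "pd_analysis_subset": {"n_total": 482_730, "n_cases": 33_674},
}


@dataclass(frozen=True)
class PowerInput:
    """Configuration of a binary-outcome power calculation."""

    n_total: int
    n_cases: int
    r2: float
    or_true: float
    alpha: float = 0.05

    def __post_init__(self):
        if not (0 < self.n_cases < self.n_total):
            raise ConfigurationError(
                f"need 0 < n_cases ({self.n_cases}) < n_total ({self.n_total})"
            )
        if not (0.0 < self.r2 < 1.0):
            raise ConfigurationError(f"r2 {self.r2} outside (0, 1)")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError(f"alpha {self.alpha} outside (0, 1)")
        if not self.or_true > 0:
            raise ConfigurationError(f"or_true {self.or_true} must be positive")


@dataclass(frozen=True)
class VarianceExplained:
    """Per-variant and total variance explained, as proportions."""

    per_variant: pd.Series  # indexed by snp_id, proportions
    total: float

    @property
    def per_variant_percent(self) -> pd.Series:
        return self.per_variant * 100.0

    @property
    def total_percent(self) -> float:
        return self.total * 100.0


def variance_explained(
    instruments: list[VariantAssociation], formula: str = "f_stat"
) -> VarianceExplained:
    """Variance in the exposure explained by each instrument and in total.

    ``formula="f_stat"`` (default) uses R² = F/(F + n − 2) with
    F = (beta/se)², the identity between the per-variant F-statistic and
    R² in a simple regression. ``formula="naive_printed"`` provides the
    alternative β²/(β² + 2·n·se²), which understates R² by roughly a
    factor of two and is included only for comparison.

    Every instrument must carry a sample size ``n``.
    """
    if formula not in ("f_stat", "naive_printed"):
        raise ConfigurationError(f"unknown R² formula {formula!r}")
    values = {}
    for v in instruments:
        if v.n is None:
            raise ConfigurationError(f"instrument {v.snp_id} has no sample size n")
        if formula == "f_stat":
            f_i = (v.beta / v.se) ** 2
            values[v.snp_id] = f_i / (f_i + v.n - 2)
        else:
            values[v.snp_id] = v.beta**2 / (v.beta**2 + 2.0 * v.n * v.se**2)
    per_variant = pd.Series(values, dtype=float)
    return VarianceExplained(per_variant=per_variant, total=float(per_variant.sum()))


def binary_power(inp: PowerInput) -> float:
    """Power to detect ``or_true`` at two-sided level ``alpha``.

    Equals ``alpha`` exactly at OR = 1 and increases as the odds ratio
    moves away from 1 in either direction.
    """
    k_frac = inp.n_cases / inp.n_total
    b = k_frac * (inp.or_true / (1.0 + k_frac * (inp.or_true - 1.0)) - 1.0)
    v = (k_frac * (1.0 - k_frac) - b * b) / (inp.n_total * inp.r2)
    ncp = b * b / v
    crit = stats.chi2.ppf(1.0 - inp.alpha, 1)
    return float(stats.ncx2.sf(crit, 1, ncp))


def detectable_or(
    n_total: int,
    n_cases: int,
    r2: float,
    target_power: float = 0.80,
    direction: str = "protective",
    alpha: float = 0.05,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> float:
    """Odds ratio detectable at ``target_power`` by bisection.

    Searches OR in (0.5, 1) for a protective effect or (1, 2) for a risk
    effect until ``|power − target_power| < tol``. Raises
    :class:`~ivmr.exceptions.BracketError` when the target power is not
    attainable inside the bracket.
    """
    if direction not in ("protective", "risk"):
        raise ConfigurationError(f"unknown direction {direction!r}")
    if not (alpha < target_power < 1.0):
        raise ConfigurationError(
            f"target_power {target_power} must lie in (alpha, 1)"
        )

    def power_at(or_value: float) -> float:
        return binary_power(
            PowerInput(n_total=n_total, n_cases=n_cases, r2=r2,
                       or_true=or_value, alpha=alpha)
        )

    lo, hi = (0.5, 1.0) if direction == "protective" else (1.0, 2.0)
    # power decreases toward OR=1 from either side; the far edge must reach it
    far = lo if direction == "protective" else hi
    if power_at(far) < target_power:
        raise BracketError(
            f"target power {target_power} not attainable for OR in [{lo}, {hi}]"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p = power_at(mid)
        if abs(p - target_power) < tol:
            return mid
        # move toward OR=1 when overpowered, away when underpowered
        overpowered = p > target_power
        if direction == "protective":
            lo, hi = (mid, hi) if overpowered else (lo, mid)
        else:
            lo, hi = (lo, mid) if overpowered else (mid, hi)
    raise BracketError(
        f"bisection did not reach |power - {target_power}| < {tol} "
        f"in {max_iter} iterations"
    )
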