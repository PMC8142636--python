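"""End-to-end analysis orchestration.

``run_analysis`` executes, per outcome: instrument selection →
harmonization → the four causal estimators (IVW, weighted median,
MR-Egger, MR-PRESSO) → heterogeneity and pleiotropy diagnostics →
an optional binary-outcome power block, and collects everything into an
:class:`AnalysisReport` that serializes to JSON and a set of TSV tables
(estimates, diagnostics, per-outcome scatter data for an Egger plot).

All stochastic components (weighted-median bootstrap, MR-PRESSO
simulations) receive deterministic sub-seeds derived from the master
seed, so two runs with identical configuration are digest-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from . import datasets
from .estimators import egger, ivw, weighted_median
from .exceptions import MRError, PipelineError
from .heterogeneity import cochran_q, egger_intercept_test
from .mr_presso import presso_global
from .power import POWER_PRESETS, detectable_or, variance_explained
from .summary_data import (
    HarmonizedSet,
    VariantAssociation,
    harmonize,
    read_associations,
    select_instruments,
)

__all__ = ["AnalysisReport", "run_analysis", "export_scatter", "reproduce_paper"]

logger = logging.getLogger("ivmr")


@dataclass
class AnalysisReport:
    """A complete, serializable analysis result."""

    metadata: dict
    harmonization: dict
    estimates: list[dict]
    diagnostics: list[dict]
    scatter: dict
    power: dict | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisReport":
        return cls(**{k: d[k] for k in
                      ("metadata", "harmonization", "estimates", "diagnostics",
                       "scatter", "power", "warnings")})

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        return cls.from_dict(json.loads(text))

    def digest(self) -> str:
        """SHA-256 over the report content, excluding volatile metadata.

        The timestamp is the only field expected to differ between two
        runs with the same configuration and seed.
        """
        d = self.to_dict()
        d["metadata"] = {k: v for k, v in d["metadata"].items() if k != "timestamp"}
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()

    def estimates_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.estimates)

    def diagnostics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.diagnostics)


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _estimate_record(outcome: str, est, alpha: float) -> dict:
    d = est.to_dict()
    return {"outcome": outcome, **d, "significant": bool(d["pvalue"] < alpha)}


def _analyse_outcome(
    label: str,
    hs: HarmonizedSet,
    n_boot: int,
    n_sim: int,
    alpha: float,
    seeds: dict[str, int],
    warnings: list[str],
) -> tuple[list[dict], dict, dict]:
    """Estimates, one diagnostics row and the scatter block for one outcome."""
    estimates: list[dict] = []
    diag_row: dict = {"outcome": label, "k": hs.k}
    scatter: dict = {
        "variants": [
            {
                "snp_id": v.snp_id,
                "beta_exp": v.beta_exp,
                "se_exp": v.se_exp,
                "beta_out": v.beta_out,
                "se_out": v.se_out,
            }
            for v in hs.variants
        ],
        "egger_slope": None,
        "egger_intercept": None,
    }

    def attempt(name, fn):
        try:
            return fn()
        except MRError as exc:
            msg = f"{label}: {name} failed: {exc}"
            warnings.append(msg)
            logger.warning(msg)
            return None

    est = attempt("ivw", lambda: ivw(hs))
    if est:
        estimates.append(_estimate_record(label, est, alpha))
    est = attempt(
        "weighted_median",
        lambda: weighted_median(hs, n_boot=n_boot, seed=seeds["weighted_median"]),
    )
    if est:
        estimates.append(_estimate_record(label, est, alpha))
    egger_fit = attempt("egger", lambda: egger(hs))
    if egger_fit:
        estimates.append(_estimate_record(label, egger_fit.slope, alpha))
        scatter["egger_slope"] = egger_fit.slope.beta
        scatter["egger_intercept"] = egger_fit.intercept.beta
    presso = attempt(
        "mr_presso", lambda: presso_global(hs, n_sim=n_sim, seed=seeds["presso"])
    )
    if presso:
        estimates.append(_estimate_record(label, presso.raw_estimate, alpha))
        if presso.outlier_indices:
            estimates.append(_estimate_record(label, presso.corrected_estimate, alpha))
        diag_row["presso_global_pvalue"] = presso.global_pvalue
        diag_row["presso_outliers"] = presso.outlier_snp_ids
    het = attempt("cochran_q", lambda: cochran_q(hs))
    if het:
        diag_row.update(
            q=het.q, df=het.df, q_pvalue=het.pvalue, i2=het.i2,
            i2_ci_low=het.i2_ci_low, i2_ci_high=het.i2_ci_high,
        )
    itest = attempt("egger_intercept", lambda: egger_intercept_test(hs, alpha=alpha))
    if itest:
        diag_row.update(
            egger_intercept=itest.estimate.beta,
            intercept_ci_low=itest.estimate.ci_low,
            intercept_ci_high=itest.estimate.ci_high,
            intercept_pvalue=itest.estimate.pvalue,
            directional_pleiotropy=itest.directional_pleiotropy,
        )
    return estimates, diag_row, scatter


def run_analysis(
    exposure: str | Path,
    outcomes: Mapping[str, str | Path] | Sequence[str | Path],
    out_dir: str | Path | None = None,
    seed: int = 0,
    n_boot: int = 1000,
    n_sim: int = 1000,
    alpha: float = 0.05,
    p_threshold: float = 5e-8,
    palindrome_eaf_window: float = 0.08,
    power_preset: str | None = None,
    power_counts: Mapping[str, int] | None = None,
    timestamp: str | None = None,
) -> AnalysisReport:
    """Run the full two-sample MR analysis of one exposure on ≥1 outcomes.

    ``outcomes`` maps labels to summary-statistic TSV paths (a bare
    sequence of paths uses each file's stem as its label). A power block
    is added when ``power_preset`` (a key of
    :data:`~ivmr.power.POWER_PRESETS`) or explicit ``power_counts``
    (``{"n_total": ..., "n_cases": ...}``) is supplied, using the total
    variance explained by the selected instruments.

    Estimator-level failures are downgraded to warnings recorded in the
    report; zero retained instruments for any outcome is a hard error.
    """
    exposure = Path(exposure)
    if isinstance(outcomes, Mapping):
        outcome_map = {str(k): Path(v) for k, v in outcomes.items()}
    else:
        outcome_map = {Path(p).stem: Path(p) for p in outcomes}
    if not outcome_map:
        raise PipelineError("at least one outcome file is required")
    missing = [str(p) for p in [exposure, *outcome_map.values()] if not p.exists()]
    if missing:
        raise PipelineError(f"input file(s) not found: {missing}")

    rng = np.random.default_rng(seed)

    def sub_seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    exposure_assocs = read_associations(exposure)
    instruments = select_instruments(exposure_assocs, p_threshold=p_threshold)
    logger.info(
        "selected %d/%d instruments at p < %g",
        len(instruments), len(exposure_assocs), p_threshold,
    )
    if not instruments:
        raise PipelineError(
            f"no instruments pass the threshold p < {p_threshold}"
        )

    warnings: list[str] = []
    estimates: list[dict] = []
    diagnostics: list[dict] = []
    scatter: dict = {}
    harmonization: dict = {}

    for label, path in outcome_map.items():
        outcome_assocs = read_associations(path)
        hs = harmonize(
            instruments,
            outcome_assocs,
            palindrome_eaf_window=palindrome_eaf_window,
            exposure_label=exposure.stem,
            outcome_label=label,
        )
        for snp_id, reason in hs.dropped:
            logger.info("%s: dropped %s (%s)", label, snp_id, reason)
        if hs.k == 0:
            raise PipelineError(f"{label}: no instruments retained after harmonization")
        harmonization[label] = {
            "k": hs.k,
            "dropped": [list(d) for d in hs.dropped],
        }
        seeds = {"weighted_median": sub_seed(), "presso": sub_seed()}
        ests, diag_row, sc = _analyse_outcome(
            label, hs, n_boot, n_sim, alpha, seeds, warnings
        )
        estimates.extend(ests)
        diagnostics.append(diag_row)
        scatter[label] = sc

    power_block = None
    if power_preset is not None or power_counts is not None:
        counts = dict(POWER_PRESETS[power_preset]) if power_preset else dict(power_counts)
        ve = variance_explained(instruments)
        power_block = {
            "preset": power_preset,
            "n_total": counts["n_total"],
            "n_cases": counts["n_cases"],
            "alpha": alpha,
            "r2_total": ve.total,
            "r2_per_variant": ve.per_variant.to_dict(),
            "detectable_or_80": detectable_or(
                counts["n_total"], counts["n_cases"], ve.total,
                target_power=0.80, direction="protective", alpha=alpha,
            ),
        }

    metadata = {
        "package": "ivmr",
        "version": _version,
        "seed": seed,
        "n_boot": n_boot,
        "n_sim": n_sim,
        "alpha": alpha,
        "p_threshold": p_threshold,
        "palindrome_eaf_window": palindrome_eaf_window,
        "timestamp": timestamp or datetime.now(timezone.utc).isoformat(),
        "inputs": {
            "exposure": {"path": str(exposure), "sha256": _sha256_file(exposure)},
            "outcomes": {
                label: {"path": str(p), "sha256": _sha256_file(p)}
                for label, p in outcome_map.items()
            },
        },
    }
    report = AnalysisReport(
        metadata=metadata,
        harmonization=harmonization,
        estimates=estimates,
        diagnostics=diagnostics,
        scatter=scatter,
        power=power_block,
        warnings=warnings,
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def _safe_label(label: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "_" for c in label)


def export_scatter(report: AnalysisReport, outcome: str) -> pd.DataFrame:
    """Figure-ready scatter data for one outcome: per-variant effects and
    SEs on both axes plus the Egger regression line (empty when k < 3)."""
    if outcome not in report.scatter:
        raise KeyError(
            f"unknown outcome {outcome!r}; have {sorted(report.scatter)}"
        )
    block = report.scatter[outcome]
    df = pd.DataFrame(block["variants"])
    df["egger_slope"] = block["egger_slope"]
    df["egger_intercept"] = block["egger_intercept"]
    return df


def write_report(report: AnalysisReport, out_dir: str | Path) -> None:
    """Write report.json, estimates.tsv, diagnostics.tsv and per-outcome
    scatter_<outcome>.tsv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_json(out / "report.json")
    report.estimates_frame().to_csv(out / "estimates.tsv", sep="\t", index=False)
    report.diagnostics_frame().to_csv(out / "diagnostics.tsv", sep="\t", index=False)
    for label in report.scatter:
        export_scatter(report, label).to_csv(
            out / f"scatter_{_safe_label(label)}.tsv", sep="\t", index=False
        )


def reproduce_paper(
    out_dir: str | Path | None = None, seed: int = 0,
    n_boot: int = 1000, n_sim: int = 1000,
) -> AnalysisReport:
    """Run the bundled vitamin C → PD / PD-AAO analysis end to end.

    Uses the packaged fixture tables for the exposure and both outcomes
    and the full-meta-analysis case/control preset for the power block.
    """
    return run_analysis(
        exposure=datasets.fixture_path("vitc_exposure"),
        outcomes={
            "PD": datasets.fixture_path("pd_outcome"),
            "PD_AAO": datasets.fixture_path("pd_aao_outcome"),
        },
        out_dir=out_dir,
        seed=seed,
        n_boot=n_boot,
        n_sim=n_sim,
        power_preset="pd_full_meta",
    )
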