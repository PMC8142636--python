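"""Exception hierarchy for ivmr.

All package-specific failures derive from :class:`MRError` so callers can
catch a single base class; configuration problems and data problems are
kept distinct from estimation problems.
"""

from __future__ import annotations


class MRError(Exception):
    """Base class for all ivmr errors."""


class ConfigurationError(MRError):
    """Bad user configuration: missing columns, invalid options."""


class VariantValidationError(MRError, ValueError):
    """One or more input rows violate the variant invariants.

    Parameters
    ----------
    message:
        Human-readable description.
    snp_ids:
        Identifiers of the offending rows (empty when unknown).
    """

    def __init__(self, message: str, snp_ids: list[str] | None = None):
        super().__init__(message)
        self.snp_ids: list[str] = list(snp_ids or [])


class UndefinedRatioError(MRError):
    """Wald ratio requested for a variant with zero exposure effect."""


class InsufficientInstrumentsError(MRError):
    """Fewer instruments than the estimator's minimum."""


class DegenerateWeightsError(MRError):
    """All inverse-variance weights are zero or non-finite."""


class BracketError(MRError):
    """Root finding target not attainable inside the search bracket."""


class PipelineError(MRError):
    """End-to-end analysis cannot proceed (missing inputs, empty set)."""
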