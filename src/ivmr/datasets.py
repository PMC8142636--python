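"""Bundled instrument fixtures: 11 plasma vitamin C instruments with their
Parkinson's disease (PD) and PD age-at-onset (AAO) outcome associations.

The exposure table holds the 11 independent genome-wide-significant
variants from a 52,018-sample plasma vitamin C GWAS (effects in SD units
on the vitamin-C-raising allele, GRCh37 coordinates). The outcome tables
hold the same variants' effects in a PD case-control GWAS (33,674 cases /
449,056 controls, log-odds) and a PD age-at-onset GWAS (n = 28,568,
years), already expressed on the vitamin-C-raising allele.
"""

from __future__ import annotations

from importlib.resources import as_file, files
from pathlib import Path

from .summary_data import VariantAssociation, read_associations

__all__ = [
    "fixture_path",
    "load_vitc_exposure",
    "load_pd_outcome",
    "load_pd_aao_outcome",
]

_FIXTURES = {
    "vitc_exposure": "vitc_exposure.tsv",
    "pd_outcome": "pd_outcome.tsv",
    "pd_aao_outcome": "pd_aao_outcome.tsv",
}


def fixture_path(name: str) -> Path:
    """Filesystem path of a bundled fixture ("vitc_exposure", "pd_outcome",
    "pd_aao_outcome")."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    resource = files("ivmr") / "data" / _FIXTURES[name]
    with as_file(resource) as path:
        return Path(path)


def load_vitc_exposure() -> list[VariantAssociation]:
    """The 11 plasma vitamin C instruments (exposure associations)."""
    return read_associations(fixture_path("vitc_exposure"))


def load_pd_outcome() -> list[VariantAssociation]:
    """The instruments' associations with Parkinson's disease (log-odds)."""
    return read_associations(fixture_path("pd_outcome"))


def load_pd_aao_outcome() -> list[VariantAssociation]:
    """The instruments' associations with PD age at onset (years)."""
    return read_associations(fixture_path("pd_aao_outcome"))
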