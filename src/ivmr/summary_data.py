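"""GWAS summary-statistic data model, TSV I/O, instrument selection and
allele harmonization for two-sample Mendelian randomization.

The unit of input is one variant's association in one GWAS
(:class:`VariantAssociation`); the unit of all downstream MR arithmetic is
an exposure/outcome pair expressed on a shared effect allele
(:class:`HarmonizedVariant`, collected into a :class:`HarmonizedSet`).

Harmonization follows the standard two-sample conventions: the exposure
record is oriented to the exposure-raising allele (so every ``beta_exp`` is
positive), the outcome record is aligned to that allele by direct match,
allele swap, or strand complement, and palindromic variants (A/T or C/G)
are resolved by comparing effect-allele frequencies between the two
studies — or dropped as ambiguous when the exposure frequency is too close
to 0.5 for frequencies to be informative.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ConfigurationError, VariantValidationError

__all__ = [
    "VariantAssociation",
    "HarmonizedVariant",
    "HarmonizedSet",
    "DEFAULT_DIALECT",
    "read_associations",
    "write_associations",
    "select_instruments",
    "swap_alleles",
    "harmonize",
]

BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: allele pairs that are their own strand complement
PALINDROMIC_PAIRS = (frozenset("AT"), frozenset("CG"))

#: canonical field name -> column name in a tab-separated input file
DEFAULT_DIALECT: dict[str, str] = {
    "snp_id": "snp",
    "chromosome": "chr",
    "position": "pos",
    "effect_allele": "ea",
    "other_allele": "nea",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pval",
    "n": "n",
}

#: columns that must be present; ``n`` is optional
_MANDATORY = ("snp_id", "chromosome", "position", "effect_allele",
              "other_allele", "eaf", "beta", "se", "pvalue")


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's summary statistics in one GWAS.

    ``beta`` is the per-allele effect of ``effect_allele`` (SD units for a
    standardized continuous exposure, log-odds for a binary outcome, years
    for age at onset); ``eaf`` is the effect-allele frequency.
    """

    snp_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int | None = None

    def __post_init__(self):
        problems = []
        if self.effect_allele not in BASES:
            problems.append(f"effect allele {self.effect_allele!r} is not one of A/C/G/T")
        if self.other_allele not in BASES:
            problems.append(f"other allele {self.other_allele!r} is not one of A/C/G/T")
        if self.effect_allele == self.other_allele:
            problems.append("effect and other allele are identical")
        if not (0.0 <= self.eaf <= 1.0):
            problems.append(f"eaf {self.eaf} outside [0, 1]")
        if not (self.se > 0):
            problems.append(f"se {self.se} is not positive")
        if not (0.0 < self.pvalue <= 1.0):
            problems.append(f"p-value {self.pvalue} outside (0, 1]")
        if not math.isfinite(self.beta):
            problems.append(f"beta {self.beta} is not finite")
        if self.n is not None and not self.n > 0:
            problems.append(f"sample size {self.n} is not positive")
        if problems:
            raise VariantValidationError(
                f"{self.snp_id}: " + "; ".join(problems), snp_ids=[self.snp_id]
            )

    @property
    def alleles(self) -> frozenset:
        return frozenset((self.effect_allele, self.other_allele))

    @property
    def is_palindromic(self) -> bool:
        return self.alleles in PALINDROMIC_PAIRS


@dataclass(frozen=True)
class HarmonizedVariant:
    """An exposure/outcome pair on the shared, exposure-raising effect allele."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float
    eaf_out: float
    flipped: bool = False
    palindromic: bool = False

    def __post_init__(self):
        if not self.beta_exp > 0:
            raise VariantValidationError(
                f"{self.snp_id}: beta_exp must be positive after orientation",
                snp_ids=[self.snp_id],
            )
        if not (self.se_exp > 0 and self.se_out > 0):
            raise VariantValidationError(
                f"{self.snp_id}: standard errors must be positive",
                snp_ids=[self.snp_id],
            )


@dataclass
class HarmonizedSet:
    """An ordered collection of harmonized exposure/outcome pairs."""

    exposure_label: str
    outcome_label: str
    variants: list[HarmonizedVariant]
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        ids = [v.snp_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise VariantValidationError("duplicate snp_ids in harmonized set", snp_ids=ids)

    @property
    def k(self) -> int:
        return len(self.variants)

    def subset(self, keep: Sequence[int]) -> "HarmonizedSet":
        """A new set restricted to the variants at positions ``keep``."""
        return HarmonizedSet(
            exposure_label=self.exposure_label,
            outcome_label=self.outcome_label,
            variants=[self.variants[i] for i in keep],
            dropped=list(self.dropped),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(v) for v in self.variants])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_dict(self) -> dict:
        return {
            "exposure_label": self.exposure_label,
            "outcome_label": self.outcome_label,
            "variants": [dataclasses.asdict(v) for v in self.variants],
            "dropped": [list(d) for d in self.dropped],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: Mapping) -> "HarmonizedSet":
        return cls(
            exposure_label=d["exposure_label"],
            outcome_label=d["outcome_label"],
            variants=[HarmonizedVariant(**v) for v in d["variants"]],
            dropped=[tuple(x) for x in d["dropped"]],
        )


def read_associations(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> list[VariantAssociation]:
    """Read variant associations from a tab-separated file with a header row.

    ``dialect`` maps canonical field names (keys of :data:`DEFAULT_DIALECT`)
    to the column names used in the file; unspecified fields fall back to the
    defaults. Alleles are upper-cased before validation. Rows violating the
    variant invariants raise a :class:`VariantValidationError` naming every
    offending variant — bad rows are reported, never silently dropped.
    """
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        unknown = set(dialect) - set(DEFAULT_DIALECT)
        if unknown:
            raise ConfigurationError(f"unknown dialect fields: {sorted(unknown)}")
        colmap.update(dialect)

    df = pd.read_csv(path, sep="\t", dtype=str)
    for fieldname in _MANDATORY:
        if colmap[fieldname] not in df.columns:
            raise ConfigurationError(
                f"mandatory column {colmap[fieldname]!r} (field {fieldname!r}) "
                f"missing from {path}"
            )
    has_n = colmap["n"] in df.columns

    records: list[VariantAssociation] = []
    errors: list[str] = []
    bad_ids: list[str] = []
    for _, row in df.iterrows():
        snp = str(row[colmap["snp_id"]]).strip()
        try:
            n_raw = row[colmap["n"]] if has_n else None
            n = None if n_raw is None or pd.isna(n_raw) else int(float(n_raw))
            records.append(
                VariantAssociation(
                    snp_id=snp,
                    chromosome=str(row[colmap["chromosome"]]).strip(),
                    position=int(float(row[colmap["position"]])),
                    effect_allele=str(row[colmap["effect_allele"]]).strip().upper(),
                    other_allele=str(row[colmap["other_allele"]]).strip().upper(),
                    eaf=float(row[colmap["eaf"]]),
                    beta=float(row[colmap["beta"]]),
                    se=float(row[colmap["se"]]),
                    pvalue=float(row[colmap["pvalue"]]),
                    n=n,
                )
            )
        except (VariantValidationError, ValueError, TypeError) as exc:
            errors.append(f"{snp}: {exc}")
            bad_ids.append(snp)
    if errors:
        raise VariantValidationError(
            f"{len(errors)} invalid row(s) in {path}:\n" + "\n".join(errors),
            snp_ids=bad_ids,
        )
    return records


def write_associations(
    assocs: Iterable[VariantAssociation],
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> None:
    """Write associations to a tab-separated file in the given dialect."""
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        colmap.update(dialect)
    rows = []
    for a in assocs:
        d = dataclasses.asdict(a)
        rows.append({colmap[k]: v for k, v in d.items()})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def select_instruments(
    assocs: Sequence[VariantAssociation], p_threshold: float = 5e-8
) -> list[VariantAssociation]:
    """Keep variants reaching the association threshold (p < ``p_threshold``).

    The conventional genome-wide significance threshold 5e-8 is the default.
    Input order is preserved; no linkage-disequilibrium pruning is performed —
    instruments are assumed independent on entry.
    """
    if not (0.0 < p_threshold <= 1.0):
        raise ConfigurationError(f"p_threshold {p_threshold} outside (0, 1]")
    return [a for a in assocs if a.pvalue < p_threshold]


def swap_alleles(v: VariantAssociation) -> VariantAssociation:
    """Re-express an association on the opposite allele.

    Swaps effect/other allele, negates beta and reflects the frequency.
    Applying it twice returns the original record exactly.
    """
    return dataclasses.replace(
        v,
        effect_allele=v.other_allele,
        other_allele=v.effect_allele,
        beta=-v.beta,
        eaf=1.0 - v.eaf,
    )


def _complement(v: VariantAssociation) -> VariantAssociation:
    """The same association read off the opposite strand (alleles complemented)."""
    return dataclasses.replace(
        v,
        effect_allele=COMPLEMENT[v.effect_allele],
        other_allele=COMPLEMENT[v.other_allele],
    )


def harmonize(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    palindrome_eaf_window: float = 0.08,
    exposure_label: str = "exposure",
    outcome_label: str = "outcome",
) -> HarmonizedSet:
    """Align outcome associations to the exposure's exposure-raising allele.

    For each variant shared between the two studies:

    1. the exposure record is oriented so its beta is positive;
    2. a non-palindromic outcome record is aligned by literal allele match,
       by allele swap (beta negated, frequency reflected), or — failing
       both — by strand complement followed by the same two checks;
    3. a palindromic record (A/T or C/G) cannot be aligned by allele labels,
       so the orientation minimising ``|eaf_exp − eaf_out|`` is chosen; the
       variant is dropped as an ambiguous palindrome when the exposure
       frequency lies within ``palindrome_eaf_window`` of 0.5, where
       frequency comparison is uninformative.

    Variants present on only one side, with incompatible alleles, or with a
    zero exposure effect are dropped with a reason; ``|retained| + |dropped|``
    always equals the number of distinct input variants.
    """
    if not (0.0 <= palindrome_eaf_window < 0.5):
        raise ConfigurationError(
            f"palindrome_eaf_window {palindrome_eaf_window} outside [0, 0.5)"
        )
    out_by_id: dict[str, VariantAssociation] = {}
    for o in outcome:
        if o.snp_id in out_by_id:
            raise VariantValidationError(
                f"duplicate outcome record for {o.snp_id}", snp_ids=[o.snp_id]
            )
        out_by_id[o.snp_id] = o

    variants: list[HarmonizedVariant] = []
    dropped: list[tuple[str, str]] = []
    seen_exp: set[str] = set()

    for e in exposure:
        if e.snp_id in seen_exp:
            raise VariantValidationError(
                f"duplicate exposure record for {e.snp_id}", snp_ids=[e.snp_id]
            )
        seen_exp.add(e.snp_id)
        if e.snp_id not in out_by_id:
            dropped.append((e.snp_id, "missing from outcome"))
            continue
        o = out_by_id[e.snp_id]

        if e.beta == 0:
            dropped.append((e.snp_id, "zero exposure effect"))
            continue
        if e.beta < 0:
            e = swap_alleles(e)

        if e.is_palindromic:
            if o.alleles != e.alleles:
                dropped.append((e.snp_id, "allele mismatch"))
                continue
            if min(e.eaf, 1.0 - e.eaf) > 0.5 - palindrome_eaf_window:
                dropped.append((e.snp_id, "ambiguous palindrome"))
                continue
            # allele labels cannot distinguish strands here; let frequency decide
            flipped = abs(e.eaf - o.eaf) > abs(e.eaf - (1.0 - o.eaf))
            aligned = swap_alleles(o) if flipped else o
            variants.append(
                HarmonizedVariant(
                    snp_id=e.snp_id,
                    effect_allele=e.effect_allele,
                    other_allele=e.other_allele,
                    beta_exp=e.beta,
                    se_exp=e.se,
                    beta_out=aligned.beta,
                    se_out=aligned.se,
                    eaf_exp=e.eaf,
                    eaf_out=aligned.eaf if not flipped else 1.0 - o.eaf,
                    flipped=flipped,
                    palindromic=True,
                )
            )
            continue

        aligned = None
        flipped = False
        for cand in (o, _complement(o)):
            if (cand.effect_allele, cand.other_allele) == (e.effect_allele, e.other_allele):
                aligned = cand
                flipped = False
                break
            if (cand.effect_allele, cand.other_allele) == (e.other_allele, e.effect_allele):
                aligned = swap_alleles(cand)
                flipped = True
                break
        if aligned is None:
            dropped.append((e.snp_id, "allele mismatch"))
            continue
        variants.append(
            HarmonizedVariant(
                snp_id=e.snp_id,
                effect_allele=e.effect_allele,
                other_allele=e.other_allele,
                beta_exp=e.beta,
                se_exp=e.se,
                beta_out=aligned.beta,
                se_out=aligned.se,
                eaf_exp=e.eaf,
                eaf_out=aligned.eaf,
                flipped=flipped,
                palindromic=False,
            )
        )

    for snp_id in out_by_id:
        if snp_id not in seen_exp:
            dropped.append((snp_id, "missing from exposure"))

    return HarmonizedSet(
        exposure_label=exposure_label,
        outcome_label=outcome_label,
        variants=variants,
        dropped=dropped,
    )
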