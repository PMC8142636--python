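"""Data model, TSV reading, instrument selection and harmonization."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivmr import (
    VariantAssociation,
    datasets,
    harmonize,
    read_associations,
    select_instruments,
    swap_alleles,
    write_associations,
)
from ivmr.exceptions import ConfigurationError, VariantValidationError


def make_assoc(**kwargs):
    defaults = dict(
        snp_id="rs1", chromosome="1", position=1000, effect_allele="A",
        other_allele="G", eaf=0.3, beta=0.1, se=0.01, pvalue=1e-10, n=1000,
    )
    defaults.update(kwargs)
    return VariantAssociation(**defaults)


class TestReadAssociations:
    def test_fixture_row_parsed(self, exposure):
        by_id = {a.snp_id: a for a in exposure}
        v = by_id["rs33972313"]
        assert v.beta == pytest.approx(0.36)
        assert v.se == pytest.approx(0.018)
        assert v.eaf == pytest.approx(0.968)
        assert v.effect_allele == "C"
        assert v.other_allele == "T"
        assert v.n == 52018
        assert len(exposure) == 11

    def test_header_only_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("snp\tchr\tpos\tea\tnea\teaf\tbeta\tse\tpval\tn\n")
        assert read_associations(p) == []

    def test_bad_allele_reported_with_snp_id(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "snp\tchr\tpos\tea\tnea\teaf\tbeta\tse\tpval\tn\n"
            "rs1\t1\t100\tA\tG\t0.5\t0.1\t0.01\t1e-9\t100\n"
            "rsBAD\t1\t200\tX\tG\t0.5\t0.1\t0.01\t1e-9\t100\n"
        )
        with pytest.raises(VariantValidationError) as err:
            read_associations(p)
        assert "rsBAD" in err.value.snp_ids

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "nocol.tsv"
        p.write_text("snp\tchr\tpos\tea\tnea\teaf\tbeta\tse\n")
        with pytest.raises(ConfigurationError, match="pval"):
            read_associations(p)

    def test_custom_dialect(self, tmp_path):
        p = tmp_path / "dialect.tsv"
        p.write_text(
            "rsid\tchr\tpos\tea\tnea\teaf\tb\tse\tpval\tn\n"
            "rs1\t1\t100\ta\tg\t0.5\t0.1\t0.01\t1e-9\t100\n"
        )
        (rec,) = read_associations(p, dialect={"snp_id": "rsid", "beta": "b"})
        assert rec.snp_id == "rs1"
        assert rec.effect_allele == "A"  # upper-cased

    def test_roundtrip_through_writer(self, tmp_path, exposure):
        p = tmp_path / "out.tsv"
        write_associations(exposure, p)
        assert read_associations(p) == exposure


class TestVariantInvariants:
    @pytest.mark.parametrize(
        "bad",
        [
            dict(effect_allele="A", other_allele="A"),
            dict(se=0.0),
            dict(se=-1.0),
            dict(eaf=1.5),
            dict(pvalue=0.0),
            dict(n=0),
        ],
    )
    def test_invalid_fields_rejected(self, bad):
        with pytest.raises(VariantValidationError):
            make_assoc(**bad)


class TestSelectInstruments:
    def test_all_fixture_variants_pass_genomewide_threshold(self, exposure):
        assert len(select_instruments(exposure, 5e-8)) == 11

    def test_threshold_below_all_p_gives_empty(self, exposure):
        assert select_instruments(exposure, 1e-300) == []

    def test_threshold_one_is_identity(self, exposure):
        assert select_instruments(exposure, 1.0) == exposure

    def test_order_preserved_and_no_mutation(self, exposure):
        kept = select_instruments(exposure, 1e-9)
        assert kept == [a for a in exposure if a.pvalue < 1e-9]


alleles = st.sampled_from("ACGT")


@st.composite
def associations(draw):
    ea = draw(alleles)
    nea = draw(alleles.filter(lambda a: a != ea))
    return make_assoc(
        effect_allele=ea,
        other_allele=nea,
        eaf=draw(st.floats(0.01, 0.99)),
        beta=draw(st.floats(-2, 2, allow_nan=False).filter(lambda b: b != 0)),
    )


class TestHarmonize:
    @settings(derandomize=True, max_examples=200)
    @given(associations())
    def test_allele_swap_is_an_involution(self, assoc):
        back = swap_alleles(swap_alleles(assoc))
        assert (back.effect_allele, back.other_allele) == (
            assoc.effect_allele, assoc.other_allele
        )
        assert back.beta == assoc.beta  # negation is exact
        assert back.eaf == pytest.approx(assoc.eaf, abs=1e-15)  # 1-(1-x): one ulp

    def test_cooriented_tables_fully_retained(self, exposure):
        hs = harmonize(exposure, datasets.load_pd_aao_outcome())
        assert hs.k == 11
        assert hs.dropped == []
        assert not any(v.flipped for v in hs.variants)
        assert sum(v.palindromic for v in hs.variants) == 1  # rs56738967

    def test_orientation_invariant(self, exposure):
        # negate some exposure betas: harmonization must restore positivity
        # and keep one literal shared effect allele per pair
        flipped_exposure = [
            swap_alleles(a) if i % 2 else a for i, a in enumerate(exposure)
        ]
        hs = harmonize(flipped_exposure, datasets.load_pd_aao_outcome())
        assert hs.k == 11
        assert all(v.beta_exp > 0 for v in hs.variants)

    def test_exposure_orientation_flips_outcome_consistently(self, exposure):
        ref = harmonize(exposure, datasets.load_pd_aao_outcome())
        hs = harmonize([swap_alleles(a) for a in exposure],
                       datasets.load_pd_aao_outcome())
        for a, b in zip(ref.variants, hs.variants):
            assert b.beta_exp == pytest.approx(a.beta_exp)
            assert b.beta_out == pytest.approx(a.beta_out)

    def test_swapped_outcome_alleles_negate_beta_and_reflect_eaf(self):
        e = make_assoc(effect_allele="A", other_allele="G", beta=0.1, eaf=0.3)
        o = make_assoc(effect_allele="G", other_allele="A", beta=0.2, eaf=0.7)
        hs = harmonize([e], [o])
        (v,) = hs.variants
        assert v.flipped
        assert v.beta_out == pytest.approx(-0.2)
        assert v.eaf_out == pytest.approx(0.3)

    def test_strand_complement_matched_before_mismatch(self):
        e = make_assoc(effect_allele="A", other_allele="G", beta=0.1)
        o = make_assoc(effect_allele="T", other_allele="C", beta=0.2, eaf=0.3)
        hs = harmonize([e], [o])
        (v,) = hs.variants
        assert not v.flipped
        assert v.beta_out == pytest.approx(0.2)
        assert hs.dropped == []

    def test_complement_plus_swap_flips(self):
        e = make_assoc(effect_allele="A", other_allele="G", beta=0.1)
        o = make_assoc(effect_allele="C", other_allele="T", beta=0.2, eaf=0.7)
        hs = harmonize([e], [o])
        (v,) = hs.variants
        assert v.flipped
        assert v.beta_out == pytest.approx(-0.2)

    def test_incompatible_alleles_dropped_with_reason(self):
        e = make_assoc(effect_allele="A", other_allele="G", beta=0.1)
        o = make_assoc(effect_allele="C", other_allele="A", beta=0.2)
        hs = harmonize([e], [o])
        assert hs.k == 0
        assert ("rs1", "allele mismatch") in hs.dropped

    def test_palindrome_resolved_by_frequency(self):
        # mirror of the fixture's C/G variant: clear frequencies, kept as-is
        e = make_assoc(effect_allele="C", other_allele="G", beta=0.041, eaf=0.321)
        o = make_assoc(effect_allele="C", other_allele="G", beta=-0.003, eaf=0.32)
        (v,) = harmonize([e], [o]).variants
        assert v.palindromic and not v.flipped
        assert v.beta_out == pytest.approx(-0.003)

    def test_palindrome_flipped_by_frequency(self):
        e = make_assoc(effect_allele="C", other_allele="G", beta=0.041, eaf=0.321)
        o = make_assoc(effect_allele="G", other_allele="C", beta=0.2, eaf=0.68)
        (v,) = harmonize([e], [o]).variants
        assert v.flipped
        assert v.beta_out == pytest.approx(-0.2)
        assert v.eaf_out == pytest.approx(0.32)

    def test_ambiguous_palindrome_dropped(self):
        e = make_assoc(effect_allele="C", other_allele="G", beta=0.1, eaf=0.50)
        o = make_assoc(effect_allele="C", other_allele="G", beta=0.2, eaf=0.5)
        hs = harmonize([e], [o])
        assert ("rs1", "ambiguous palindrome") in hs.dropped

    def test_palindrome_window_is_configurable(self):
        e = make_assoc(effect_allele="C", other_allele="G", beta=0.1, eaf=0.45)
        o = make_assoc(effect_allele="C", other_allele="G", beta=0.2, eaf=0.45)
        assert harmonize([e], [o], palindrome_eaf_window=0.08).k == 0
        assert harmonize([e], [o], palindrome_eaf_window=0.02).k == 1

    def test_conservation_of_variants(self, exposure):
        # outcome missing two variants plus one extra outcome-only variant
        outcome = datasets.load_pd_aao_outcome()[:-2]
        extra = make_assoc(snp_id="rs999", effect_allele="A", other_allele="G")
        hs = harmonize(exposure, outcome + [extra])
        all_ids = {a.snp_id for a in exposure} | {a.snp_id for a in outcome} | {"rs999"}
        assert hs.k + len(hs.dropped) == len(all_ids)
        reasons = dict(hs.dropped)
        assert reasons["rs999"] == "missing from exposure"

    def test_serialization_roundtrip(self, aao_set):
        from ivmr import HarmonizedSet

        clone = HarmonizedSet.from_dict(aao_set.to_dict())
        assert clone.variants == aao_set.variants
        assert clone.dropped == aao_set.dropped

    def test_tsv_export_has_one_row_per_variant(self, aao_set, tmp_path):
        aao_set.to_tsv(tmp_path / "hs.tsv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "hs.tsv", sep="\t")
        assert len(df) == aao_set.k
        assert "beta_exp" in df.columns
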