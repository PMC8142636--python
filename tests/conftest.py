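import pytest

from ivmr import HarmonizedSet, HarmonizedVariant, datasets, harmonize


@pytest.fixture(scope="session")
def exposure():
    return datasets.load_vitc_exposure()


@pytest.fixture(scope="session")
def pd_set(exposure):
    return harmonize(exposure, datasets.load_pd_outcome(),
                     exposure_label="vitc", outcome_label="PD")


@pytest.fixture(scope="session")
def aao_set(exposure):
    return harmonize(exposure, datasets.load_pd_aao_outcome(),
                     exposure_label="vitc", outcome_label="PD_AAO")


@pytest.fixture
def make_set():
    """Factory for toy harmonized sets from raw effect/SE vectors."""

    def _make(bx, by, sy, sx=None, label="toy"):
        sx = sx if sx is not None else [s / 10 for s in sy]
        variants = [
            HarmonizedVariant(
                snp_id=f"rs{i + 1}",
                effect_allele="A",
                other_allele="G",
                beta_exp=float(bx[i]),
                se_exp=float(sx[i]),
                beta_out=float(by[i]),
                se_out=float(sy[i]),
                eaf_exp=0.5,
                eaf_out=0.5,
            )
            for i in range(len(bx))
        ]
        return HarmonizedSet(exposure_label="exp", outcome_label=label,
                             variants=variants)

    return _make
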