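import numpy as np
import pytest

from edsp.models import IndividualRecord, MarkerDef, TraitModel


@pytest.fixture
def default_model() -> TraitModel:
    return TraitModel.from_variance_fractions()


@pytest.fixture
def strong_model() -> TraitModel:
    """QTL explaining half the variance of both traits."""
    return TraitModel.from_variance_fractions(
        qtl_frac_sbp=0.5, qtl_frac_dbp=0.5, polygenic_frac=0.2)


@pytest.fixture
def linked_marker() -> MarkerDef:
    return MarkerDef(name="M_LINKED", chromosome="17", theta=0.0,
                     n_alleles=8)


@pytest.fixture
def unlinked_marker() -> MarkerDef:
    return MarkerDef(name="M_FAR", chromosome="11", theta=0.5, n_alleles=8)


def make_sib(family="F1", iid="S1", sbp=None, dbp=None, sex="female",
             age=40.0, genotypes=None) -> IndividualRecord:
    return IndividualRecord(
        family_id=family, individual_id=iid, father_id="P1",
        mother_id="P2", sex=sex, age=age, sbp=sbp, dbp=dbp,
        genotypes=genotypes or [])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
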