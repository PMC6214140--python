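import numpy as np
import pytest

from prdmscan.maf import (
    DomainInterval,
    DomainKind,
    MutationRecord,
    ProteinModel,
    VariantClass,
    VariantType,
)


def make_record(
    gene="PRDM9",
    patient="TCGA-AB-0001",
    cohort="ACC",
    vclass=VariantClass.MISSENSE,
    position=None,
    aa=None,
    sift=None,
    polyphen=None,
    genomic_position=1000,
    alt="A",
    vtype=VariantType.SNP,
):
    """Terse MutationRecord factory for tests."""
    return MutationRecord(
        gene_symbol=gene,
        patient_id=patient,
        cohort=cohort,
        variant_class=vclass,
        variant_type=vtype,
        chromosome="chr1",
        genomic_position=genomic_position,
        ref_allele="G",
        alt_allele=alt,
        protein_position=position,
        aa_change=aa,
        sift_score=sift,
        polyphen_score=polyphen,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def single_pr_model():
    """Length-10 protein whose PR domain covers residues 1-5 (f = 0.5)."""
    return ProteinModel(
        "PRDM9", 10, (DomainInterval("PR", DomainKind.PR, 1, 5),)
    )


@pytest.fixture
def znf_model():
    """A 600-aa protein with one PR domain and two zinc fingers."""
    return ProteinModel(
        "PRDM6",
        600,
        (
            DomainInterval("PR", DomainKind.PR, 50, 169),
            DomainInterval("ZnF1", DomainKind.ZNF, 300, 322),
            DomainInterval("ZnF2", DomainKind.ZNF, 400, 422),
        ),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
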