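"""MAF-dialect reading, writing, subsetting and record validation."""

import gzip

import pytest
from hypothesis import given, settings, strategies as st

from prdmscan.exceptions import MafFormatError, ValidationError
from prdmscan.maf import (
    NONSYNONYMOUS_CLASSES,
    MutationRecord,
    VariantClass,
    VariantType,
    dedupe_records,
    patient_from_barcode,
    read_cohort_catalog,
    read_maf,
    subset_records,
    write_cohort_catalog,
    write_maf,
)
from tests.conftest import make_record

HEADER = (
    "Hugo_Symbol\tChromosome\tStart_Position\tReference_Allele\t"
    "Tumor_Seq_Allele2\tVariant_Classification\tVariant_Type\t"
    "Tumor_Sample_Barcode\tProtein_position\tHGVSp_Short\t"
    "SIFT_score\tPolyPhen_score"
)


def write_toy_maf(path, rows, header=HEADER, comment=True):
    lines = (["#version synthetic"] if comment else []) + [header] + rows
    path.write_text("\n".join(lines) + "\n")


def test_read_maf_maps_fields_and_classes(tmp_path):
    path = tmp_path / "toy.maf"
    write_toy_maf(path, [
        "PRDM9\tchr5\t100\tG\tA\tMissense_Mutation\tSNP\tTCGA-OR-A5J1-01A-11D\t237\tp.S237L\t0.01\t0.9",
        "PRDM9\tchr5\t200\tC\tT\tSilent\tSNP\tTCGA-OR-A5J2-01A\t\t\t\t",
        "PRDM2\tchr1\t300\tT\t-\tFrame_Shift_Del\tDEL\tTCGA-OR-A5J3-01B\t50\t\t\t",
    ])
    records = read_maf(path, "ACC")
    assert [r.variant_class for r in records] == [
        VariantClass.MISSENSE, VariantClass.SILENT, VariantClass.FRAME_SHIFT_DEL,
    ]
    first = records[0]
    assert first.patient_id == "TCGA-OR-A5J1"
    assert first.protein_position == 237
    assert first.aa_change == "S237L"
    assert first.sift_score == 0.01 and first.polyphen_score == 0.9
    assert first.cohort == "ACC"
    assert records[2].variant_type is VariantType.DEL


def test_read_maf_header_only_gives_empty_list(tmp_path):
    path = tmp_path / "empty.maf"
    write_toy_maf(path, [])
    assert read_maf(path, "ACC") == []


def test_read_maf_missing_mandatory_column_names_it(tmp_path):
    path = tmp_path / "bad.maf"
    path.write_text("Hugo_Symbol\tVariant_Type\tTumor_Sample_Barcode\nPRDM9\tSNP\tX\n")
    with pytest.raises(MafFormatError, match="Variant_Classification"):
        read_maf(path, "ACC")


def test_read_maf_unknown_class_maps_to_catchall_with_warning(tmp_path, caplog):
    path = tmp_path / "dialect.maf"
    write_toy_maf(path, [
        "PRDM9\tchr5\t100\tG\tA\tTargeted_Region\tSNP\tTCGA-OR-A5J1-01A\t\t\t\t",
    ])
    with caplog.at_level("WARNING"):
        records = read_maf(path, "ACC")
    assert records[0].variant_class is VariantClass.OTHER
    assert "Targeted_Region" in caplog.text


def test_read_maf_unparseable_protein_position_kept_absent(tmp_path, caplog):
    path = tmp_path / "pos.maf"
    write_toy_maf(path, [
        "PRDM9\tchr5\t100\tG\tA\tMissense_Mutation\tSNP\tTCGA-OR-A5J1-01A\t?intron\t\t\t",
    ])
    with caplog.at_level("WARNING"):
        records = read_maf(path, "ACC")
    assert records[0].protein_position is None
    assert "unparseable" in caplog.text


def test_read_maf_tolerates_gzip(tmp_path):
    path = tmp_path / "toy.maf.gz"
    content = HEADER + "\nPRDM9\tchr5\t100\tG\tA\tSilent\tSNP\tTCGA-OR-A5J1-01A\t\t\t\t\n"
    with gzip.open(path, "wt") as fh:
        fh.write(content)
    assert len(read_maf(path, "ACC")) == 1


def test_patient_from_barcode_is_first_twelve_characters():
    assert patient_from_barcode("TCGA-OR-A5J1-01A-11D-A29I-10") == "TCGA-OR-A5J1"


@st.composite
def _records(draw):
    vclass = draw(st.sampled_from(list(VariantClass)))
    pos = draw(st.one_of(st.none(), st.integers(1, 2000)))
    aa = f"S{pos}L" if pos is not None and draw(st.booleans()) else None
    return make_record(
        gene=draw(st.sampled_from(["PRDM1", "PRDM9", "ZFPM1"])),
        patient=f"TCGA-XX-{draw(st.integers(0, 9999)):04d}",
        cohort=draw(st.sampled_from(["ACC", "COAD"])),
        vclass=vclass,
        position=pos,
        aa=aa,
        sift=draw(st.one_of(st.none(), st.floats(0, 1, allow_nan=False))),
        polyphen=draw(st.one_of(st.none(), st.floats(0, 1, allow_nan=False))),
        genomic_position=draw(st.integers(1, 10**8)),
    )


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.lists(_records(), max_size=30))
def test_write_then_read_round_trips_all_modeled_fields(tmp_path_factory, records):
    path = tmp_path_factory.mktemp("maf") / "rt.maf"
    write_maf(records, path)
    back = read_maf(path, records[0].cohort if records else "ACC")
    assert len(back) == len(records)
    for a, b in zip(records, back):
        for field in ("gene_symbol", "patient_id", "variant_class", "variant_type",
                      "genomic_position", "ref_allele", "alt_allele",
                      "protein_position", "aa_change"):
            if field == "patient_id":
                continue  # checked below; cohort is reader-supplied
            assert getattr(a, field) == getattr(b, field), field
        assert a.patient_id == b.patient_id
        for field in ("sift_score", "polyphen_score"):
            va, vb = getattr(a, field), getattr(b, field)
            assert (va is None) == (vb is None)
            if va is not None:
                assert vb == pytest.approx(va)


def test_subset_records_filters_exactly(record_factory):
    records = [
        record_factory(gene="PRDM9"), record_factory(gene="PRDM9"),
        record_factory(gene="PRDM1"), record_factory(gene="ZFPM1"),
        record_factory(gene="PRDM2"),
    ]
    assert len(subset_records(records, genes={"PRDM9"})) == 2
    assert subset_records(records, genes=set()) == []
    universe = {r.gene_symbol for r in records}
    assert subset_records(records, genes=universe) == records


def test_subset_union_over_disjoint_cohorts(record_factory):
    a = [record_factory(cohort="ACC", patient=f"TCGA-AA-{i:04d}") for i in range(3)]
    b = [record_factory(cohort="COAD", patient=f"TCGA-BB-{i:04d}") for i in range(2)]
    both = subset_records(a + b, cohorts={"ACC", "COAD"})
    assert both == subset_records(a + b, cohorts={"ACC"}) + subset_records(
        a + b, cohorts={"COAD"}
    )


def test_dedupe_collapses_same_patient_gene_position_alt(record_factory):
    r1 = record_factory(genomic_position=100, alt="A")
    dup = record_factory(genomic_position=100, alt="A")
    other_allele = record_factory(genomic_position=100, alt="T")
    deduped = dedupe_records([r1, dup, other_allele])
    assert deduped == [r1, other_allele]


def test_record_invariants_enforced():
    with pytest.raises(ValidationError):
        make_record(genomic_position=0)
    with pytest.raises(ValidationError):
        make_record(sift=1.5, position=5)
    with pytest.raises(ValidationError):
        MutationRecord("G", "P", "ACC", VariantClass.MISSENSE, aa_change="S5L")


def test_cohort_catalog_round_trip(tmp_path):
    path = tmp_path / "catalog.tsv"
    write_cohort_catalog({"ACC": 92, "LAML": 196}, path)
    assert read_cohort_catalog(path) == {"ACC": 92, "LAML": 196}


def test_nonsynonymous_set_excludes_silent_and_noncoding():
    assert VariantClass.SILENT not in NONSYNONYMOUS_CLASSES
    assert VariantClass.INTRON not in NONSYNONYMOUS_CLASSES
    assert VariantClass.MISSENSE in NONSYNONYMOUS_CLASSES
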