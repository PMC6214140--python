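"""Class counts, patient frequency matrices, multi-hit and oncostrip tables."""

import pytest
from hypothesis import given, settings, strategies as st

from prdmscan.exceptions import ConfigurationError, DomainInputError
from prdmscan.landscape import (
    any_mutated_fraction,
    multi_hit_summary,
    mutation_class_counts,
    oncostrip_matrix,
    patient_frequency_matrix,
)
from prdmscan.maf import VariantClass
from tests.conftest import make_record


def patients(n, prefix="TCGA-AA"):
    return [f"{prefix}-{i:04d}" for i in range(n)]


class TestClassCounts:
    def test_empty_input_gives_empty_table(self):
        assert mutation_class_counts([]).empty

    def test_silent_fraction_from_hand_enumeration(self):
        records = [make_record(gene="PRDM6") for _ in range(3)] + [
            make_record(gene="PRDM6", vclass=VariantClass.SILENT)
        ]
        table = mutation_class_counts(records)
        row = table.loc["PRDM6"]
        assert row["total"] == 4
        assert row["silent_fraction"] == pytest.approx(0.25)

    def test_all_silent_boundary(self):
        records = [make_record(vclass=VariantClass.SILENT) for _ in range(10)]
        assert mutation_class_counts(records).loc["PRDM9", "silent_fraction"] == 1.0

    def test_column_sums_conserve_global_class_totals(self, rng):
        classes = [c for c in VariantClass if c is not VariantClass.OTHER]
        records = [
            make_record(
                gene=f"G{rng.integers(5)}",
                vclass=classes[rng.integers(len(classes))],
            )
            for _ in range(200)
        ]
        table = mutation_class_counts(records)
        for vc in classes:
            global_count = sum(1 for r in records if r.variant_class is vc)
            assert table[vc.value].sum() == global_count
        assert table["total"].sum() == len(records)

    def test_zero_rows_only_with_explicit_universe(self):
        records = [make_record(gene="PRDM9")]
        assert list(mutation_class_counts(records).index) == ["PRDM9"]
        table = mutation_class_counts(records, gene_universe=["PRDM9", "PRDM6"])
        assert table.loc["PRDM6", "total"] == 0


class TestFrequencyMatrix:
    def test_single_patient_full_penetrance(self):
        records = [make_record(gene="PRDM2", cohort="ACC")]
        matrix = patient_frequency_matrix(records, {"ACC": 1})
        assert matrix.loc["ACC", "PRDM2"] == 100.0

    def test_patient_counted_once_despite_multiple_hits(self):
        one = [make_record(gene="PRDM2", genomic_position=100)]
        three = [
            make_record(gene="PRDM2", genomic_position=100 + i) for i in range(3)
        ]
        catalog = {"ACC": 10}
        assert patient_frequency_matrix(one, catalog).equals(
            patient_frequency_matrix(three, catalog)
        )

    def test_rounding_to_one_decimal_half_up(self):
        records = [
            make_record(gene="PRDM9", patient=p, cohort="ACC")
            for p in patients(2)
        ]
        matrix = patient_frequency_matrix(records, {"ACC": 92})
        assert matrix.loc["ACC", "PRDM9"] == 2.2  # 100*2/92 = 2.1739

    def test_cohort_missing_from_catalog_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            patient_frequency_matrix([make_record(cohort="ACC")], {"COAD": 5})

    def test_silent_mutations_do_not_qualify(self):
        records = [make_record(vclass=VariantClass.SILENT, cohort="ACC")]
        matrix = patient_frequency_matrix(records, {"ACC": 4})
        assert matrix.empty or (matrix.to_numpy() == 0).all()

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 3))
    def test_record_duplication_idempotence(self, copies):
        base = [
            make_record(gene="PRDM9", patient=p, cohort="ACC", genomic_position=50)
            for p in patients(4)
        ]
        duplicated = base * (copies + 1)
        assert patient_frequency_matrix(base, {"ACC": 10}).equals(
            patient_frequency_matrix(duplicated, {"ACC": 10})
        )


class TestAnyMutatedFraction:
    def test_acc_style_fraction(self):
        records = [
            make_record(gene="ZFPM1", patient=p, cohort="ACC") for p in patients(51)
        ]
        assert any_mutated_fraction(records, "ACC", 92, ["ZFPM1"]) == 55.43

    def test_laml_style_fraction(self):
        records = [
            make_record(gene="PRDM9", patient=p, cohort="LAML") for p in patients(2)
        ]
        assert any_mutated_fraction(records, "LAML", 196, ["PRDM9"]) == 1.02

    def test_no_qualifying_patients_is_zero(self):
        assert any_mutated_fraction([], "ACC", 92, ["PRDM9"]) == 0.0

    def test_nonpositive_patient_count_rejected(self):
        with pytest.raises(DomainInputError):
            any_mutated_fraction([], "ACC", 0, ["PRDM9"])

    def test_dominates_per_gene_frequency(self, rng):
        genes = ["PRDM1", "PRDM9", "ZFPM1"]
        records = [
            make_record(
                gene=genes[rng.integers(3)],
                patient=f"TCGA-AA-{rng.integers(20):04d}",
                cohort="ACC",
                genomic_position=int(rng.integers(1, 10**6)),
            )
            for _ in range(60)
        ]
        matrix = patient_frequency_matrix(records, {"ACC": 25}, gene_universe=genes)
        combined = any_mutated_fraction(records, "ACC", 25, genes)
        assert combined >= matrix.loc["ACC"].max() - 0.05  # rounding slack


class TestMultiHit:
    def test_coad_style_ratio(self):
        records = []
        for i, p in enumerate(patients(18)):
            records.append(make_record(gene="ZFPM1", cohort="COAD", patient=p,
                                       genomic_position=100))
            if i < 11:
                records.append(make_record(gene="ZFPM1", cohort="COAD", patient=p,
                                           genomic_position=200))
        assert multi_hit_summary(records, "ZFPM1", "COAD") == (11, 18, 61)

    def test_half_up_rounding_of_ten_elevenths(self):
        records = []
        for i, p in enumerate(patients(11)):
            records.append(make_record(gene="ZFPM1", cohort="READ", patient=p,
                                       genomic_position=100))
            if i < 10:
                records.append(make_record(gene="ZFPM1", cohort="READ", patient=p,
                                           genomic_position=200))
        # 100*10/11 = 90.9..., half-up to 91
        assert multi_hit_summary(records, "ZFPM1", "READ")[2] == 91

    def test_all_single_hit_gives_zero_percent(self):
        records = [make_record(patient=p) for p in patients(5)]
        assert multi_hit_summary(records, "PRDM9", "ACC") == (0, 5, 0)

    def test_undefined_when_nobody_mutated(self):
        assert multi_hit_summary([], "PRDM9", "ACC") == (0, 0, None)


class TestOncostrip:
    def test_two_mutations_same_gene_label_multi_hit(self):
        records = [
            make_record(genomic_position=100),
            make_record(vclass=VariantClass.NONSENSE, genomic_position=200),
        ]
        matrix = oncostrip_matrix(records, "ACC", ["PRDM9"])
        assert matrix.loc["TCGA-AB-0001", "PRDM9"] == "Multi_Hit"

    def test_single_silent_record_leaves_cell_empty(self):
        records = [make_record(vclass=VariantClass.SILENT)]
        matrix = oncostrip_matrix(records, "ACC", ["PRDM9"])
        assert matrix.empty or (matrix == "").all().all()

    def test_no_records_gives_all_empty_matrix(self):
        assert oncostrip_matrix([], "ACC", ["PRDM9"]).empty

    def test_single_hit_shows_its_class(self):
        records = [make_record(vclass=VariantClass.FRAME_SHIFT_DEL)]
        matrix = oncostrip_matrix(records, "ACC", ["PRDM9", "PRDM1"])
        assert matrix.loc["TCGA-AB-0001", "PRDM9"] == "Frame_Shift_Del"
        assert matrix.loc["TCGA-AB-0001", "PRDM1"] == ""
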