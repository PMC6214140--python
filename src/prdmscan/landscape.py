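"""Mutation-landscape summaries.

Patient-level counting is the rule throughout: a patient carrying several
qualifying mutations in one gene contributes once to frequency cells, and
"multi-hit" means two or more qualifying mutations in the same gene of the
same patient's tumor.  Percentages follow the printed-table conventions of
pan-cancer mutation reports: frequency-matrix cells to one decimal,
cohort-level any-mutated fractions to two decimals, multi-hit percentages
to the nearest integer, all half-up.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import round_half_up
from .exceptions import ConfigurationError, DomainInputError
from .maf import NONSYNONYMOUS_CLASSES, MutationRecord, VariantClass

_COUNTED_CLASSES = [vc for vc in VariantClass if vc is not VariantClass.OTHER]


def mutation_class_counts(
    records: Sequence[MutationRecord],
    gene_universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-gene counts of each variant class, with totals and silent fraction.

    Every record is counted exactly once (catch-all ``Other`` records are
    excluded).  Genes absent from the records appear as all-zero rows only
    when ``gene_universe`` is given.
    """
    genes = list(gene_universe) if gene_universe is not None else sorted(
        {r.gene_symbol for r in records if r.variant_class is not VariantClass.OTHER}
    )
    counts = {g: {vc.value: 0 for vc in _COUNTED_CLASSES} for g in genes}
    for r in records:
        if r.variant_class is VariantClass.OTHER:
            continue
        if r.gene_symbol not in counts:
            if gene_universe is not None:
                continue
            counts[r.gene_symbol] = {vc.value: 0 for vc in _COUNTED_CLASSES}
        counts[r.gene_symbol][r.variant_class.value] += 1
    df = pd.DataFrame(
        counts.values(), index=list(counts), columns=[vc.value for vc in _COUNTED_CLASSES]
    ).reindex(genes)
    df.index.name = "gene_symbol"
    df["total"] = df.sum(axis=1)
    df["silent_fraction"] = df[VariantClass.SILENT.value].where(df["total"] > 0, 0) / df[
        "total"
    ].where(df["total"] > 0, 1)
    return df


def _qualifying_patients_by_gene(
    records: Sequence[MutationRecord],
    qualifying_classes: frozenset[VariantClass] | set[VariantClass],
) -> dict[tuple[str, str], set[str]]:
    """(cohort, gene) -> set of patients with >=1 qualifying mutation."""
    out: dict[tuple[str, str], set[str]] = {}
    for r in records:
        if r.variant_class in qualifying_classes:
            out.setdefault((r.cohort, r.gene_symbol), set()).add(r.patient_id)
    return out


def patient_frequency_matrix(
    records: Sequence[MutationRecord],
    catalog: Mapping[str, int],
    qualifying_classes: frozenset[VariantClass] = NONSYNONYMOUS_CLASSES,
    gene_universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Cohort x gene matrix of the percentage of patients mutated in each gene.

    Cell (c, g) = 100 * |{patients of c with >=1 qualifying mutation in g}|
    / n_patients(c), rounded half-up to one decimal.  Multiple mutations in
    one patient count once.
    """
    for r in records:
        if r.cohort not in catalog:
            raise ConfigurationError(
                f"cohort {r.cohort!r} appears in records but not in the catalog"
            )
    by_cell = _qualifying_patients_by_gene(records, qualifying_classes)
    cohorts = sorted(catalog)
    genes = list(gene_universe) if gene_universe is not None else sorted(
        {g for (_, g) in by_cell}
    )
    data = [
        [
            round_half_up(100.0 * len(by_cell.get((c, g), ())) / catalog[c], 1)
            for g in genes
        ]
        for c in cohorts
    ]
    df = pd.DataFrame(data, index=cohorts, columns=genes)
    df.index.name = "cohort"
    return df


def any_mutated_fraction(
    records: Sequence[MutationRecord],
    cohort: str,
    n_patients: int,
    gene_set: Iterable[str],
    qualifying_classes: frozenset[VariantClass] = NONSYNONYMOUS_CLASSES,
) -> float:
    """Percentage of cohort patients with >=1 qualifying mutation in any listed gene."""
    if n_patients <= 0:
        raise DomainInputError(f"n_patients must be positive, got {n_patients}")
    genes = set(gene_set)
    patients = {
        r.patient_id
        for r in records
        if r.cohort == cohort
        and r.gene_symbol in genes
        and r.variant_class in qualifying_classes
    }
    return round_half_up(100.0 * len(patients) / n_patients, 2)


def multi_hit_summary(
    records: Sequence[MutationRecord],
    gene: str,
    cohort: str,
    qualifying_classes: frozenset[VariantClass] = NONSYNONYMOUS_CLASSES,
) -> tuple[int, int, int | None]:
    """(n_multi_hit, n_mutated, percentage) of patients with >=2 hits in ``gene``.

    The percentage is 100 * n_multi_hit / n_mutated rounded half-up to the
    nearest integer, or ``None`` when no patient is mutated.
    """
    per_patient: dict[str, int] = {}
    for r in records:
        if (
            r.cohort == cohort
            and r.gene_symbol == gene
            and r.variant_class in qualifying_classes
        ):
            per_patient[r.patient_id] = per_patient.get(r.patient_id, 0) + 1
    n_mutated = len(per_patient)
    n_multi = sum(1 for n in per_patient.values() if n >= 2)
    if n_mutated == 0:
        return 0, 0, None
    return n_multi, n_mutated, int(round_half_up(100.0 * n_multi / n_mutated, 0))


MULTI_HIT_LABEL = "Multi_Hit"


def oncostrip_matrix(
    records: Sequence[MutationRecord],
    cohort: str,
    gene_set: Iterable[str],
    qualifying_classes: frozenset[VariantClass] = NONSYNONYMOUS_CLASSES,
) -> pd.DataFrame:
    """Patient x gene label matrix for waterfall-style visualization.

    A cell holds the variant class when the patient carries exactly one
    qualifying mutation in that gene, ``Multi_Hit`` for two or more, and
    the empty string otherwise.
    """
    genes = list(gene_set)
    cells: dict[str, dict[str, list[VariantClass]]] = {}
    for r in records:
        if (
            r.cohort == cohort
            and r.gene_symbol in set(genes)
            and r.variant_class in qualifying_classes
        ):
            cells.setdefault(r.patient_id, {}).setdefault(r.gene_symbol, []).append(
                r.variant_class
            )
    patients = sorted(cells)
    data = []
    for p in patients:
        row = []
        for g in genes:
            classes = cells.get(p, {}).get(g, [])
            if not classes:
                row.append("")
            elif len(classes) == 1:
                row.append(classes[0].value)
            else:
                row.append(MULTI_HIT_LABEL)
        data.append(row)
    df = pd.DataFrame(data, index=patients, columns=genes)
    df.index.name = "patient_id"
    return df


def oncostrip_long(matrix: pd.DataFrame) -> pd.DataFrame:
    """Long-format (patient, gene, label) view of a non-empty oncostrip matrix."""
    long = matrix.stack().reset_index()
    long.columns = ["patient_id", "gene_symbol", "label"]
    return long[long["label"] != ""].reset_index(drop=True)
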