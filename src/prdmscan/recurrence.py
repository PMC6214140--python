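"""Cross-cohort recurrent mutations, within-cohort hotspots, lollipop tables.

A mutation identity for recurrence is the gene plus the exact amino-acid
change for substitutions carrying one (missense/nonsense style), or the
gene plus protein position plus variant class for indel/splice events,
whose allele strings may differ while describing the same recurrent
lesion.  A hotspot is a protein position mutated in at least
``min_patients`` distinct patients of one cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .maf import (
    NONSYNONYMOUS_CLASSES,
    MutationRecord,
    ProteinModel,
    VariantClass,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RecurrentMutation:
    gene_symbol: str
    label: str                      # aa_change, or "pos<N>:<class>" for indel/splice
    protein_position: int | None
    cohorts: frozenset[str]
    n_patients_total: int

    @property
    def n_cohorts(self) -> int:
        return len(self.cohorts)


@dataclass(frozen=True)
class Hotspot:
    gene_symbol: str
    protein_position: int
    cohort: str
    n_patients: int
    aa_changes: frozenset[str] = field(default_factory=frozenset)


_SUBSTITUTION_CLASSES = {
    VariantClass.MISSENSE,
    VariantClass.NONSENSE,
    VariantClass.NONSTOP,
}


def mutation_identity(record: MutationRecord) -> tuple[str, str, int | None] | None:
    """Normalized identity (gene, label, position) or None if unidentifiable."""
    if record.variant_class in _SUBSTITUTION_CLASSES and record.aa_change:
        return (record.gene_symbol, record.aa_change, record.protein_position)
    if record.protein_position is not None:
        return (
            record.gene_symbol,
            f"pos{record.protein_position}:{record.variant_class.value}",
            record.protein_position,
        )
    return None


def recurrent_mutations(
    records: Sequence[MutationRecord],
    min_cohorts: int = 4,
    qualifying_classes: frozenset[VariantClass] = NONSYNONYMOUS_CLASSES,
) -> list[RecurrentMutation]:
    """Mutations observed in at least ``min_cohorts`` distinct cohorts.

    The default threshold of 4 renders "recurrent in more than three tumor
    types".  Output is sorted by cohort count descending, then gene, then
    position.
    """
    if min_cohorts < 2:
        raise ValueError("min_cohorts must be >= 2")
    groups: dict[tuple, dict] = {}
    for r in records:
        if r.variant_class not in qualifying_classes:
            continue
        ident = mutation_identity(r)
        if ident is None:
            continue
        g = groups.setdefault(ident, {"cohorts": set(), "patients": set()})
        g["cohorts"].add(r.cohort)
        g["patients"].add((r.cohort, r.patient_id))
    out = [
        RecurrentMutation(
            gene_symbol=gene,
            label=label,
            protein_position=pos,
            cohorts=frozenset(g["cohorts"]),
            n_patients_total=len(g["patients"]),
        )
        for (gene, label, pos), g in groups.items()
        if len(g["cohorts"]) >= min_cohorts
    ]
    out.sort(key=lambda m: (-m.n_cohorts, m.gene_symbol, m.protein_position or 0, m.label))
    return out


def cohort_hotspots(
    records: Sequence[MutationRecord],
    cohort: str,
    min_patients: int = 3,
    qualifying_classes: frozenset[VariantClass] = NONSYNONYMOUS_CLASSES,
) -> list[Hotspot]:
    """Protein positions mutated in >= ``min_patients`` distinct patients."""
    if min_patients < 2:
        raise ValueError("min_patients must be >= 2")
    per_pos: dict[tuple[str, int], dict] = {}
    for r in records:
        if (
            r.cohort != cohort
            or r.variant_class not in qualifying_classes
            or r.protein_position is None
        ):
            continue
        g = per_pos.setdefault((r.gene_symbol, r.protein_position),
                               {"patients": set(), "aa": set()})
        g["patients"].add(r.patient_id)
        if r.aa_change:
            g["aa"].add(r.aa_change)
    out = [
        Hotspot(
            gene_symbol=gene,
            protein_position=pos,
            cohort=cohort,
            n_patients=len(g["patients"]),
            aa_changes=frozenset(g["aa"]),
        )
        for (gene, pos), g in per_pos.items()
        if len(g["patients"]) >= min_patients
    ]
    out.sort(key=lambda h: (-h.n_patients, h.gene_symbol, h.protein_position))
    return out


def lollipop_table(
    records: Sequence[MutationRecord],
    gene: str,
    protein_model: ProteinModel,
    qualifying_classes: frozenset[VariantClass] = NONSYNONYMOUS_CLASSES,
) -> pd.DataFrame:
    """Per-position mutation counts with domain labels for lollipop plots.

    Rows: (protein_position, count, domain, domain_kind, out_of_bounds).
    Positions beyond the protein length are kept but flagged, with a
    logged warning.
    """
    if protein_model.gene_symbol != gene:
        raise ValueError(
            f"protein model is for {protein_model.gene_symbol}, not {gene}"
        )
    counts: dict[int, int] = {}
    for r in records:
        if (
            r.gene_symbol == gene
            and r.variant_class in qualifying_classes
            and r.protein_position is not None
        ):
            counts[r.protein_position] = counts.get(r.protein_position, 0) + 1
    rows = []
    for pos in sorted(counts):
        oob = pos > protein_model.length_aa
        if oob:
            logger.warning(
                "%s: mutated position %d beyond protein length %d",
                gene, pos, protein_model.length_aa,
            )
        dom = None if oob else protein_model.domain_at(pos)
        rows.append({
            "protein_position": pos,
            "count": counts[pos],
            "domain": dom.name if dom else "",
            "domain_kind": dom.kind.value if dom else "",
            "out_of_bounds": oob,
        })
    return pd.DataFrame(
        rows,
        columns=["protein_position", "count", "domain", "domain_kind", "out_of_bounds"],
    )
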