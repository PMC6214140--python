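"""Deleterious-versus-tolerated classification of somatic mutations.

Missense calls rest on predictor scores consumed from the input table: a
SIFT score in [0, 0.05] and/or a PolyPhen score in [0.5, 1] marks the
mutation deleterious (a single qualifying score suffices; a missing score
never disqualifies when the other qualifies).  Frameshift, in-frame
insertion/deletion, stop-gained, stop-lost, start-lost, splice-site, UTR
and intron variants are deleterious by category; UTR/intron membership in
that list is a deliberate, toggleable convention.  Silent mutations are
tolerated.  Missense with no score at all is UNSCORED and, by default,
counted with the tolerated side in summaries (the conservative choice).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from ._util import round_half_up
from .exceptions import ValidationError
from .maf import MutationRecord, VariantClass


class Call(str, enum.Enum):
    DELETERIOUS = "DELETERIOUS"
    TOLERATED = "TOLERATED"
    UNSCORED = "UNSCORED"


class Reason(str, enum.Enum):
    SIFT = "SIFT"
    POLYPHEN = "POLYPHEN"
    BOTH = "BOTH"
    CATEGORY = "CATEGORY"
    NONE = "NONE"


@dataclass(frozen=True, slots=True)
class DeleteriousCall:
    record: MutationRecord
    call: Call
    reason: Reason

    def __post_init__(self) -> None:
        if self.call is Call.DELETERIOUS and self.reason is Reason.NONE:
            raise ValidationError("a DELETERIOUS call requires a reason")


SIFT_DELETERIOUS = (0.0, 0.05)     # closed interval
POLYPHEN_DELETERIOUS = (0.5, 1.0)  # closed interval

#: Classes deleterious by category alone (no score needed).
CATEGORY_DELETERIOUS: frozenset[VariantClass] = frozenset({
    VariantClass.FRAME_SHIFT_DEL,
    VariantClass.FRAME_SHIFT_INS,
    VariantClass.IN_FRAME_DEL,
    VariantClass.IN_FRAME_INS,
    VariantClass.NONSENSE,
    VariantClass.NONSTOP,
    VariantClass.TRANSLATION_START_SITE,
    VariantClass.SPLICE_SITE,
    VariantClass.UTR3,
    VariantClass.UTR5,
    VariantClass.INTRON,
})

#: The category set with the biologically debatable UTR/intron entries removed.
CATEGORY_DELETERIOUS_CODING_ONLY: frozenset[VariantClass] = CATEGORY_DELETERIOUS - {
    VariantClass.UTR3, VariantClass.UTR5, VariantClass.INTRON,
}


def _score_ok(value: float | None, name: str) -> None:
    if value is not None and not (0.0 <= value <= 1.0):
        raise ValidationError(f"{name} outside [0, 1]: {value}")


def classify_deleterious(
    record: MutationRecord,
    category_deleterious: frozenset[VariantClass] = CATEGORY_DELETERIOUS,
) -> DeleteriousCall:
    """Classify one mutation as DELETERIOUS, TOLERATED or UNSCORED."""
    _score_ok(record.sift_score, "sift_score")
    _score_ok(record.polyphen_score, "polyphen_score")

    if record.variant_class in category_deleterious:
        return DeleteriousCall(record, Call.DELETERIOUS, Reason.CATEGORY)
    if record.variant_class is not VariantClass.MISSENSE:
        # Silent, RNA and any class outside the category list is tolerated.
        return DeleteriousCall(record, Call.TOLERATED, Reason.NONE)

    sift, poly = record.sift_score, record.polyphen_score
    sift_hit = sift is not None and SIFT_DELETERIOUS[0] <= sift <= SIFT_DELETERIOUS[1]
    poly_hit = (
        poly is not None and POLYPHEN_DELETERIOUS[0] <= poly <= POLYPHEN_DELETERIOUS[1]
    )
    if sift_hit and poly_hit:
        return DeleteriousCall(record, Call.DELETERIOUS, Reason.BOTH)
    if sift_hit:
        return DeleteriousCall(record, Call.DELETERIOUS, Reason.SIFT)
    if poly_hit:
        return DeleteriousCall(record, Call.DELETERIOUS, Reason.POLYPHEN)
    if sift is None and poly is None:
        return DeleteriousCall(record, Call.UNSCORED, Reason.NONE)
    return DeleteriousCall(record, Call.TOLERATED, Reason.NONE)


def deleterious_summary(
    records: Sequence[MutationRecord],
    gene_universe: Iterable[str] | None = None,
    unscored_as_tolerated: bool = True,
    category_deleterious: frozenset[VariantClass] = CATEGORY_DELETERIOUS,
) -> pd.DataFrame:
    """Per-gene deleterious counts, totals and percentage (one decimal).

    ``n_total`` counts every modeled record of the gene, silent included.
    With ``unscored_as_tolerated=False``, unscored missense records are
    dropped from both numerator and denominator instead of counting as
    tolerated.
    """
    genes = list(gene_universe) if gene_universe is not None else sorted(
        {r.gene_symbol for r in records if r.variant_class is not VariantClass.OTHER}
    )
    gset = set(genes)
    n_del: dict[str, int] = {g: 0 for g in genes}
    n_tot: dict[str, int] = {g: 0 for g in genes}
    for r in records:
        if r.variant_class is VariantClass.OTHER or r.gene_symbol not in gset:
            continue
        call = classify_deleterious(r, category_deleterious)
        if call.call is Call.UNSCORED and not unscored_as_tolerated:
            continue
        n_tot[r.gene_symbol] += 1
        if call.call is Call.DELETERIOUS:
            n_del[r.gene_symbol] += 1
    rows = []
    for g in genes:
        pct = round_half_up(100.0 * n_del[g] / n_tot[g], 1) if n_tot[g] else None
        rows.append({
            "gene_symbol": g,
            "n_deleterious": n_del[g],
            "n_total": n_tot[g],
            "pct_deleterious": pct,
        })
    return pd.DataFrame(rows).set_index("gene_symbol")
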