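"""Record model and I/O for MAF-dialect somatic mutation tables.

The reader targets the TCGA Mutation Annotation Format dialect: a
tab-separated table with ``#``-prefixed comment lines, free column order,
and at minimum the ``Hugo_Symbol``, ``Variant_Classification``,
``Variant_Type`` and ``Tumor_Sample_Barcode`` columns.  Patient identity is
the first 12 characters of the sample barcode (the TCGA patient level), so
``TCGA-OR-A5J1-01A-11D-...`` becomes patient ``TCGA-OR-A5J1``.

Protein consequences (protein position, amino-acid change, SIFT/PolyPhen
scores) are consumed as optional annotation columns; this package never
runs a variant effect predictor itself.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ConfigurationError, MafFormatError, ValidationError

logger = logging.getLogger(__name__)

PATIENT_BARCODE_LEN = 12

#: The 19 PRDM-family HGNC symbols (PRDM1-16 plus ZNF408/PRDM17 and the
#: two FOG genes ZFPM1/ZFPM2), the default gene universe of the pipeline.
PRDM_GENES: tuple[str, ...] = (
    "PRDM1", "PRDM2", "MECOM", "PRDM4", "PRDM5", "PRDM6", "PRDM7",
    "PRDM8", "PRDM9", "PRDM10", "PRDM11", "PRDM12", "PRDM13", "PRDM14",
    "PRDM15", "PRDM16", "ZNF408", "ZFPM1", "ZFPM2",
)


class VariantType(str, enum.Enum):
    SNP = "SNP"
    INS = "INS"
    DEL = "DEL"


class VariantClass(str, enum.Enum):
    """MAF Variant_Classification labels modeled by the pipeline.

    ``OTHER`` is a catch-all for dialect-specific labels we do not model;
    such records are kept on read (so round-trips are lossless) but are
    excluded from every downstream count.
    """

    MISSENSE = "Missense_Mutation"
    SILENT = "Silent"
    NONSENSE = "Nonsense_Mutation"
    NONSTOP = "Nonstop_Mutation"
    SPLICE_SITE = "Splice_Site"
    FRAME_SHIFT_DEL = "Frame_Shift_Del"
    FRAME_SHIFT_INS = "Frame_Shift_Ins"
    IN_FRAME_DEL = "In_Frame_Del"
    IN_FRAME_INS = "In_Frame_Ins"
    TRANSLATION_START_SITE = "Translation_Start_Site"
    UTR3 = "3'UTR"
    UTR5 = "5'UTR"
    INTRON = "Intron"
    RNA = "RNA"
    OTHER = "Other"


#: Protein-altering classes: the qualifying set for patient-frequency,
#: hotspot and recurrence summaries ("non-synonymous" in the conventional
#: sense).
NONSYNONYMOUS_CLASSES: frozenset[VariantClass] = frozenset({
    VariantClass.MISSENSE,
    VariantClass.NONSENSE,
    VariantClass.NONSTOP,
    VariantClass.SPLICE_SITE,
    VariantClass.FRAME_SHIFT_DEL,
    VariantClass.FRAME_SHIFT_INS,
    VariantClass.IN_FRAME_DEL,
    VariantClass.IN_FRAME_INS,
    VariantClass.TRANSLATION_START_SITE,
})


@dataclass(frozen=True, slots=True)
class MutationRecord:
    """One somatic variant call in one tumor sample."""

    gene_symbol: str
    patient_id: str
    cohort: str
    variant_class: VariantClass
    variant_type: VariantType = VariantType.SNP
    chromosome: str = ""
    genomic_position: int = 1
    ref_allele: str = "N"
    alt_allele: str = "N"
    protein_position: int | None = None
    aa_change: str | None = None
    sift_score: float | None = None
    polyphen_score: float | None = None

    def __post_init__(self) -> None:
        if self.genomic_position < 1:
            raise ValidationError(
                f"genomic_position must be >= 1, got {self.genomic_position}"
            )
        if self.protein_position is not None and self.protein_position < 1:
            raise ValidationError(
                f"protein_position must be >= 1, got {self.protein_position}"
            )
        if self.aa_change is not None and self.protein_position is None:
            raise ValidationError(
                f"aa_change {self.aa_change!r} given without a protein position"
            )
        for name in ("sift_score", "polyphen_score"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")


class DomainKind(str, enum.Enum):
    PR = "PR"
    ZNF = "ZnF"
    OTHER = "OTHER"


@dataclass(frozen=True, slots=True)
class DomainInterval:
    """A named protein domain, 1-based closed interval in amino acids."""

    name: str
    kind: DomainKind
    start_aa: int
    end_aa: int

    def __post_init__(self) -> None:
        if not (1 <= self.start_aa <= self.end_aa):
            raise ValidationError(
                f"domain {self.name}: invalid interval [{self.start_aa}, {self.end_aa}]"
            )

    def __len__(self) -> int:
        return self.end_aa - self.start_aa + 1

    def contains(self, pos: int) -> bool:
        return self.start_aa <= pos <= self.end_aa


@dataclass(frozen=True)
class ProteinModel:
    """Canonical protein isoform: length plus non-overlapping domain intervals."""

    gene_symbol: str
    length_aa: int
    domains: tuple[DomainInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.length_aa < 1:
            raise ValidationError(f"{self.gene_symbol}: length_aa must be positive")
        object.__setattr__(self, "domains", tuple(self.domains))
        for d in self.domains:
            if d.end_aa > self.length_aa:
                raise ValidationError(
                    f"{self.gene_symbol}: domain {d.name} ends at {d.end_aa} "
                    f"beyond protein length {self.length_aa}"
                )
        ordered = sorted(self.domains, key=lambda d: d.start_aa)
        for a, b in zip(ordered, ordered[1:]):
            if b.start_aa <= a.end_aa:
                raise ValidationError(
                    f"{self.gene_symbol}: domains {a.name} and {b.name} overlap"
                )

    def pr_domains(self) -> tuple[DomainInterval, ...]:
        return tuple(d for d in self.domains if d.kind is DomainKind.PR)

    def domain_at(self, pos: int) -> DomainInterval | None:
        for d in self.domains:
            if d.contains(pos):
                return d
        return None


MANDATORY_COLUMNS = (
    "Hugo_Symbol",
    "Variant_Classification",
    "Variant_Type",
    "Tumor_Sample_Barcode",
)

_SCORE_RE = re.compile(r"\(?([0-9]*\.?[0-9]+)\)?\s*$")


def patient_from_barcode(barcode: str) -> str:
    """TCGA patient id: the first three barcode fields (12 characters)."""
    return str(barcode)[:PATIENT_BARCODE_LEN]


def _parse_int(value) -> int | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if not s or s in {".", "-", "NA", "nan"}:
        return None
    # VEP-style "237/606" (position/length) is accepted.
    s = s.split("/")[0]
    try:
        return int(float(s))
    except ValueError:
        return None


def _parse_score(value) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if not s or s in {".", "NA", "nan"}:
        return None
    try:
        return float(s)
    except ValueError:
        # VEP-style "deleterious(0.01)" annotations
        m = _SCORE_RE.search(s)
        return float(m.group(1)) if m else None


def read_maf(path: str | Path, cohort: str) -> list[MutationRecord]:
    """Read one MAF-dialect file into :class:`MutationRecord` objects.

    One record per data row, in file order.  ``#`` comment lines are
    skipped and gzip input is transparent.  Unknown
    ``Variant_Classification`` labels map to :attr:`VariantClass.OTHER`
    with a logged warning; an unparseable protein position is kept as
    absent, also with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, compression="infer")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise MafFormatError(f"{path}: missing mandatory column(s) {missing}")

    known = {vc.value: vc for vc in VariantClass}
    records: list[MutationRecord] = []
    for row in df.itertuples(index=False):
        get = lambda col, default=None: getattr(row, col, default)  # noqa: E731
        raw_class = str(getattr(row, "Variant_Classification"))
        vclass = known.get(raw_class)
        if vclass is None:
            logger.warning(
                "%s: unknown Variant_Classification %r mapped to catch-all 'Other'",
                path.name, raw_class,
            )
            vclass = VariantClass.OTHER
        raw_ppos = get("Protein_position")
        ppos = _parse_int(raw_ppos)
        if ppos is None and raw_ppos is not None and str(raw_ppos).strip() not in {
            "", ".", "-", "NA", "nan",
        }:
            logger.warning(
                "%s: unparseable protein position %r kept as absent", path.name, raw_ppos
            )
        aa = get("HGVSp_Short")
        if aa is not None and (pd.isna(aa) or not str(aa).strip()):
            aa = None
        if aa is not None:
            aa = str(aa).removeprefix("p.")
        if aa is not None and ppos is None:
            # aa_change requires a position (type invariant); derive or drop.
            m = re.search(r"(\d+)", aa)
            ppos = int(m.group(1)) if m else None
            if ppos is None:
                aa = None
        records.append(
            MutationRecord(
                gene_symbol=str(getattr(row, "Hugo_Symbol")),
                patient_id=patient_from_barcode(getattr(row, "Tumor_Sample_Barcode")),
                cohort=cohort,
                variant_class=vclass,
                variant_type=VariantType(str(getattr(row, "Variant_Type"))),
                chromosome=str(get("Chromosome", "") or ""),
                genomic_position=_parse_int(get("Start_Position")) or 1,
                ref_allele=str(get("Reference_Allele", "N") or "N"),
                alt_allele=str(get("Tumor_Seq_Allele2", "N") or "N"),
                protein_position=ppos,
                aa_change=aa,
                sift_score=_parse_score(get("SIFT_score")),
                polyphen_score=_parse_score(get("PolyPhen_score")),
            )
        )
    return records


def write_maf(records: Iterable[MutationRecord], path: str | Path) -> None:
    """Write records as a MAF-dialect table (inverse of :func:`read_maf`)."""
    rows = []
    for r in records:
        rows.append({
            "Hugo_Symbol": r.gene_symbol,
            "Chromosome": r.chromosome,
            "Start_Position": r.genomic_position,
            "Reference_Allele": r.ref_allele,
            "Tumor_Seq_Allele2": r.alt_allele,
            "Variant_Classification": r.variant_class.value,
            "Variant_Type": r.variant_type.value,
            "Tumor_Sample_Barcode": f"{r.patient_id}-01A",
            "Protein_position": "" if r.protein_position is None else r.protein_position,
            "HGVSp_Short": "" if r.aa_change is None else f"p.{r.aa_change}",
            "SIFT_score": "" if r.sift_score is None else r.sift_score,
            "PolyPhen_score": "" if r.polyphen_score is None else r.polyphen_score,
        })
    cols = ["Hugo_Symbol", "Chromosome", "Start_Position", "Reference_Allele",
            "Tumor_Seq_Allele2", "Variant_Classification", "Variant_Type",
            "Tumor_Sample_Barcode", "Protein_position", "HGVSp_Short",
            "SIFT_score", "PolyPhen_score"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def subset_records(
    records: Sequence[MutationRecord],
    genes: Iterable[str] | None = None,
    cohorts: Iterable[str] | None = None,
) -> list[MutationRecord]:
    """Records whose gene/cohort fall in the given sets (None = no filter); stable order."""
    gset = None if genes is None else set(genes)
    cset = None if cohorts is None else set(cohorts)
    return [
        r for r in records
        if (gset is None or r.gene_symbol in gset)
        and (cset is None or r.cohort in cset)
    ]


def dedupe_records(records: Sequence[MutationRecord]) -> list[MutationRecord]:
    """Collapse duplicate calls of the same event in the same patient.

    Two records are duplicates when patient, gene, genomic position and
    alternate allele coincide; the first occurrence wins.  Patient-level
    summaries count patients, not calls, so duplicated calls (e.g. from
    overlapping callers) must not inflate per-patient mutation counts.
    """
    seen: set[tuple] = set()
    out: list[MutationRecord] = []
    for r in records:
        key = (r.patient_id, r.gene_symbol, r.genomic_position, r.alt_allele)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def read_cohort_catalog(path: str | Path) -> dict[str, int]:
    """Read a TSV with ``cohort`` and ``n_patients`` columns into a dict."""
    df = pd.read_csv(path, sep="\t", dtype={"cohort": str}, compression="infer")
    for col in ("cohort", "n_patients"):
        if col not in df.columns:
            raise MafFormatError(f"{path}: cohort catalog lacks column {col!r}")
    catalog = dict(zip(df["cohort"], df["n_patients"].astype(int)))
    for cohort, n in catalog.items():
        if n <= 0:
            raise ValidationError(f"cohort {cohort}: n_patients must be positive")
    return catalog


def write_cohort_catalog(catalog: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"cohort": list(catalog), "n_patients": [catalog[c] for c in catalog]}
    ).to_csv(path, sep="\t", index=False)


def validate_catalog(records: Sequence[MutationRecord], catalog: Mapping[str, int]) -> None:
    """Check that every cohort's patient count covers its mutated patients."""
    mutated: dict[str, set[str]] = {}
    for r in records:
        mutated.setdefault(r.cohort, set()).add(r.patient_id)
    for cohort, patients in mutated.items():
        if cohort not in catalog:
            raise ConfigurationError(f"cohort {cohort!r} is missing from the cohort catalog")
        if catalog[cohort] < len(patients):
            raise ValidationError(
                f"cohort {cohort}: catalog lists {catalog[cohort]} patients but "
                f"{len(patients)} distinct mutated patients observed"
            )


def read_domain_table(path: str | Path) -> dict[str, ProteinModel]:
    """Read the per-gene protein/domain annotation TSV.

    Expected columns: ``gene_symbol``, ``length_aa``, ``domain_name``,
    ``domain_kind`` (PR, ZnF or OTHER), ``start_aa``, ``end_aa``.  Genes
    without domains carry one row with empty domain fields.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, compression="infer")
    needed = {"gene_symbol", "length_aa", "domain_name", "domain_kind", "start_aa", "end_aa"}
    missing = needed - set(df.columns)
    if missing:
        raise MafFormatError(f"{path}: domain table lacks column(s) {sorted(missing)}")
    models: dict[str, ProteinModel] = {}
    for gene, grp in df.groupby("gene_symbol", sort=False):
        length = int(float(grp["length_aa"].iloc[0]))
        domains = []
        for row in grp.itertuples(index=False):
            if not str(row.domain_name).strip() or str(row.domain_name) == "nan":
                continue
            domains.append(
                DomainInterval(
                    name=str(row.domain_name),
                    kind=DomainKind(str(row.domain_kind)),
                    start_aa=int(float(row.start_aa)),
                    end_aa=int(float(row.end_aa)),
                )
            )
        models[str(gene)] = ProteinModel(str(gene), length, tuple(domains))
    return models


def write_domain_table(models: Mapping[str, ProteinModel], path: str | Path) -> None:
    rows = []
    for gene, m in models.items():
        if not m.domains:
            rows.append({"gene_symbol": gene, "length_aa": m.length_aa,
                         "domain_name": "", "domain_kind": "", "start_aa": "", "end_aa": ""})
        for d in m.domains:
            rows.append({"gene_symbol": gene, "length_aa": m.length_aa,
                         "domain_name": d.name, "domain_kind": d.kind.value,
                         "start_aa": d.start_aa, "end_aa": d.end_aa})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


__all__ = [
    "MutationRecord", "VariantClass", "VariantType", "DomainKind",
    "DomainInterval", "ProteinModel", "NONSYNONYMOUS_CLASSES", "PRDM_GENES",
    "read_maf", "write_maf", "subset_records", "dedupe_records",
    "patient_from_barcode", "read_cohort_catalog", "write_cohort_catalog",
    "validate_catalog", "read_domain_table", "write_domain_table",
]
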