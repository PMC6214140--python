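"""Synthetic cohorts with planted truth for every pipeline stage.

The mutation simulator emulates TCGA-style cohort structure: per-cohort
patient barcodes, per-gene mutation records with variant class, protein
position and predictor scores, plus optionally planted hotspots (a
fraction of a cohort's patients mutated inside a narrow window, with a
configurable multi-hit rate) and PR-domain enrichment (deleterious
missense placed at an elevated rate inside the PR domain).  The
expression simulator draws paired tumor/normal counts from a negative
binomial with per-pair library-size variation and a planted log2 fold
change per gene.  Both return the planted truth alongside the data, and
one global seed expands into independent child streams so each stage is
reproducible on its own.

The bundled protein models are SYNTHETIC: plausible lengths and domain
layouts for the 19 PRDM-family genes (PR domain near the N-terminus,
zinc-finger repeats toward the C-terminus, none for the two FOG genes),
not curated annotation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .expression import PairedCounts
from .maf import (
    PRDM_GENES,
    DomainInterval,
    DomainKind,
    MutationRecord,
    ProteinModel,
    VariantClass,
    VariantType,
)

AA = "ACDEFGHIKLMNPQRSTVWY"
BASES = "ACGT"

#: Default variant-class mixture, shaped like pan-cancer exome calls
#: (about a quarter silent, missense dominating, indels rare).
DEFAULT_CLASS_MIXTURE: dict[VariantClass, float] = {
    VariantClass.MISSENSE: 0.545,
    VariantClass.SILENT: 0.267,
    VariantClass.NONSENSE: 0.045,
    VariantClass.SPLICE_SITE: 0.030,
    VariantClass.FRAME_SHIFT_DEL: 0.033,
    VariantClass.FRAME_SHIFT_INS: 0.002,
    VariantClass.IN_FRAME_DEL: 0.009,
    VariantClass.IN_FRAME_INS: 0.004,
    VariantClass.NONSTOP: 0.005,
    VariantClass.TRANSLATION_START_SITE: 0.005,
    VariantClass.UTR3: 0.015,
    VariantClass.UTR5: 0.015,
    VariantClass.INTRON: 0.020,
    VariantClass.RNA: 0.005,
}

_CODING = {
    VariantClass.MISSENSE, VariantClass.SILENT, VariantClass.NONSENSE,
    VariantClass.NONSTOP, VariantClass.FRAME_SHIFT_DEL,
    VariantClass.FRAME_SHIFT_INS, VariantClass.IN_FRAME_DEL,
    VariantClass.IN_FRAME_INS, VariantClass.SPLICE_SITE,
}
_DEL_TYPE = {VariantClass.FRAME_SHIFT_DEL, VariantClass.IN_FRAME_DEL}
_INS_TYPE = {VariantClass.FRAME_SHIFT_INS, VariantClass.IN_FRAME_INS}


@dataclass(frozen=True)
class PlantedHotspot:
    gene: str
    cohort: str
    window: tuple[int, int]          # 1-based inclusive protein positions
    fraction: float                  # fraction of cohort patients hit


@dataclass(frozen=True)
class PlantedEnrichment:
    gene: str
    rel_rate: float                  # relative deleterious-missense rate inside PR


@dataclass(frozen=True)
class MutSimConfig:
    cohorts: tuple[tuple[str, int], ...]
    genes: tuple[ProteinModel, ...]
    background_rate: float = 0.01            # expected mutations per patient-gene
    class_mixture: Mapping[VariantClass, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIXTURE)
    )
    hotspots: tuple[PlantedHotspot, ...] = ()
    enrichments: tuple[PlantedEnrichment, ...] = ()
    multi_hit_rate: float = 0.0
    deleterious_missense_rate: float = 0.45  # P(background missense scores deleterious)
    unscored_rate: float = 0.03              # P(missense carries no score at all)
    seed: int | None = None

    def validate(self) -> None:
        gene_models = {g.gene_symbol: g for g in self.genes}
        cohort_codes = {c for c, _ in self.cohorts}
        for code, n in self.cohorts:
            if n <= 0:
                raise ValidationError(f"cohort {code}: n_patients must be positive")
        if self.background_rate < 0:
            raise ValidationError("background_rate must be >= 0")
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9 or any(p < 0 for p in self.class_mixture.values()):
            raise ValidationError(f"class mixture must be probabilities summing to 1, sum={total}")
        for rate_name in ("multi_hit_rate", "deleterious_missense_rate", "unscored_rate"):
            v = getattr(self, rate_name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{rate_name} must lie in [0, 1], got {v}")
        for h in self.hotspots:
            if h.gene not in gene_models:
                raise ConfigurationError(f"hotspot gene {h.gene} has no protein model")
            if h.cohort not in cohort_codes:
                raise ConfigurationError(f"hotspot cohort {h.cohort} not declared")
            lo, hi = h.window
            if not (1 <= lo <= hi <= gene_models[h.gene].length_aa):
                raise ValidationError(
                    f"hotspot window {h.window} outside protein {h.gene}"
                )
            if not (0.0 <= h.fraction <= 1.0):
                raise ValidationError(f"hotspot fraction must lie in [0, 1]")
        for e in self.enrichments:
            if e.gene not in gene_models:
                raise ConfigurationError(f"enrichment gene {e.gene} has no protein model")
            if not gene_models[e.gene].pr_domains():
                raise ConfigurationError(
                    f"enrichment gene {e.gene} has no PR domain to enrich"
                )
            if e.rel_rate < 0:
                raise ValidationError("enrichment rel_rate must be >= 0")


def _barcode(cohort: str, i: int) -> str:
    site = (cohort[:2] + "XX")[:2]
    return f"TCGA-{site}-{i:04d}"


def _chromosome(gene: str) -> str:
    return f"chr{(sum(ord(c) for c in gene) % 22) + 1}"


def _hotspot_aa_change(pos: int) -> str:
    # deterministic per position, so the same hotspot lesion is the same
    # recurrence identity in every cohort
    return f"{AA[pos % 20]}{pos}{AA[(pos * 7 + 3) % 20]}"


class _GeneSampler:
    """Per-gene position samplers (uniform and PR-enriched)."""

    def __init__(self, model: ProteinModel, rel_rate: float):
        self.model = model
        L = model.length_aa
        w = np.ones(L)
        for d in model.pr_domains():
            w[d.start_aa - 1 : d.end_aa] = rel_rate
        self.enriched_p = w / w.sum()

    def draw(self, rng: np.random.Generator, enriched: bool) -> int:
        if enriched:
            return int(rng.choice(self.model.length_aa, p=self.enriched_p)) + 1
        return int(rng.integers(1, self.model.length_aa + 1))


def _scores(
    rng: np.random.Generator, deleterious: bool, unscored_rate: float
) -> tuple[float | None, float | None]:
    if rng.random() < unscored_rate:
        return None, None
    if deleterious:
        return float(rng.uniform(0.0, 0.05)), float(rng.uniform(0.5, 1.0))
    return float(rng.uniform(0.06, 1.0)), float(rng.uniform(0.0, 0.49))


def _background_record(
    rng: np.random.Generator,
    score_rng: np.random.Generator,
    gene: ProteinModel,
    sampler: _GeneSampler,
    patient: str,
    cohort: str,
    vclass: VariantClass,
    config: MutSimConfig,
    has_enrichment: bool,
) -> MutationRecord:
    ppos: int | None = None
    aa: str | None = None
    sift = poly = None
    vtype = VariantType.SNP
    ref, alt = BASES[rng.integers(0, 4)], ""
    alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
    if vclass in _DEL_TYPE:
        vtype, alt = VariantType.DEL, "-"
    elif vclass in _INS_TYPE:
        vtype, ref = VariantType.INS, "-"
    if vclass in _CODING:
        if vclass is VariantClass.TRANSLATION_START_SITE:
            ppos = 1
        elif vclass is VariantClass.MISSENSE:
            deleterious = score_rng.random() < config.deleterious_missense_rate
            ppos = sampler.draw(rng, enriched=deleterious and has_enrichment)
            aa = f"{AA[ppos % 20]}{ppos}{AA[int(rng.integers(0, 20))]}"
            sift, poly = _scores(score_rng, deleterious, config.unscored_rate)
        else:
            ppos = sampler.draw(rng, enriched=False)
            if vclass is VariantClass.NONSENSE:
                aa = f"{AA[ppos % 20]}{ppos}*"
    return MutationRecord(
        gene_symbol=gene.gene_symbol,
        patient_id=patient,
        cohort=cohort,
        variant_class=vclass,
        variant_type=vtype,
        chromosome=_chromosome(gene.gene_symbol),
        genomic_position=int(rng.integers(10_000, 200_000_000)),
        ref_allele=ref,
        alt_allele=alt,
        protein_position=ppos,
        aa_change=aa,
        sift_score=sift,
        polyphen_score=poly,
    )


def simulate_maf(config: MutSimConfig) -> tuple[list[MutationRecord], dict]:
    """Generate mutation records plus a truth table of every planted event."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_bg, rng_scores, rng_hot = (np.random.default_rng(s) for s in ss.spawn(3))

    models = {g.gene_symbol: g for g in config.genes}
    enrich = {e.gene: e.rel_rate for e in config.enrichments}
    samplers = {
        name: _GeneSampler(model, enrich.get(name, 1.0))
        for name, model in models.items()
    }
    classes = list(config.class_mixture)
    probs = np.array([config.class_mixture[c] for c in classes], dtype=float)
    probs = probs / probs.sum()

    records: list[MutationRecord] = []
    truth: dict = {"hotspots": [], "enrichments": [
        {"gene": e.gene, "rel_rate": e.rel_rate} for e in config.enrichments
    ], "multi_hit_patients": []}

    for cohort, n_pat in config.cohorts:
        patients = [_barcode(cohort, i) for i in range(n_pat)]
        for gene_name, model in models.items():
            sampler = samplers[gene_name]
            if config.background_rate > 0:
                n_muts = rng_bg.poisson(config.background_rate, size=n_pat)
                for pi in np.nonzero(n_muts)[0]:
                    for _ in range(int(n_muts[pi])):
                        vclass = classes[
                            int(rng_bg.choice(len(classes), p=probs))
                        ]
                        records.append(_background_record(
                            rng_bg, rng_scores, model, sampler, patients[pi],
                            cohort, vclass, config, gene_name in enrich,
                        ))

    for h in config.hotspots:
        model = models[h.gene]
        lo, hi = h.window
        planted_patients = []
        for cohort, n_pat in config.cohorts:
            if cohort != h.cohort:
                continue
            for i in range(n_pat):
                if rng_hot.random() >= h.fraction:
                    continue
                patient = _barcode(cohort, i)
                n_hits = 2 if rng_hot.random() < config.multi_hit_rate else 1
                for _ in range(n_hits):
                    pos = int(rng_hot.integers(lo, hi + 1))
                    sift, poly = _scores(rng_hot, True, 0.0)
                    records.append(MutationRecord(
                        gene_symbol=h.gene,
                        patient_id=patient,
                        cohort=cohort,
                        variant_class=VariantClass.MISSENSE,
                        variant_type=VariantType.SNP,
                        chromosome=_chromosome(h.gene),
                        genomic_position=int(rng_hot.integers(10_000, 200_000_000)),
                        ref_allele="G",
                        alt_allele="A",
                        protein_position=pos,
                        aa_change=_hotspot_aa_change(pos),
                        sift_score=sift,
                        polyphen_score=poly,
                    ))
                planted_patients.append({"patient": patient, "n_hits": n_hits})
                if n_hits > 1:
                    truth["multi_hit_patients"].append(
                        {"gene": h.gene, "cohort": cohort, "patient": patient}
                    )
        truth["hotspots"].append({
            "gene": h.gene, "cohort": h.cohort, "window": list(h.window),
            "fraction": h.fraction, "n_patients_planted": len(planted_patients),
        })
    return records, truth


@dataclass(frozen=True)
class ExprSimConfig:
    n_genes: int
    n_pairs: int
    baseline_mean: float = 100.0
    dispersion: float = 0.1
    logfc: tuple[float, ...] | None = None   # planted log2 FC, zeros when None
    libsize_sigma: float = 0.2               # lognormal sigma of library factors
    gene_names: tuple[str, ...] | None = None
    seed: int | None = None

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if self.n_pairs < 3:
            raise ValidationError("n_pairs must be >= 3 for a paired design")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")
        if self.baseline_mean <= 0:
            raise ValidationError("baseline_mean must be > 0")
        if self.logfc is not None and len(self.logfc) != self.n_genes:
            raise ValidationError("logfc vector length must equal n_genes")
        if self.gene_names is not None and len(self.gene_names) != self.n_genes:
            raise ValidationError("gene_names length must equal n_genes")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with var = mu + dispersion * mu^2 (size = 1/dispersion)."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_paired_counts(config: ExprSimConfig) -> tuple[PairedCounts, np.ndarray]:
    """Paired tumor/normal NB counts with a planted per-gene log2 fold change."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    logfc = np.zeros(config.n_genes) if config.logfc is None else np.asarray(
        config.logfc, dtype=float
    )
    lib_t = rng.lognormal(0.0, config.libsize_sigma, size=config.n_pairs)
    lib_n = rng.lognormal(0.0, config.libsize_sigma, size=config.n_pairs)
    base = np.full(config.n_genes, config.baseline_mean)
    mu_n = base[:, None] * lib_n[None, :]
    mu_t = (base * 2.0 ** logfc)[:, None] * lib_t[None, :]
    tumor = _nb_draw(rng, mu_t, config.dispersion)
    normal = _nb_draw(rng, mu_n, config.dispersion)
    genes = (
        tuple(config.gene_names)
        if config.gene_names is not None
        else tuple(f"G{i:04d}" for i in range(config.n_genes))
    )
    pairs = tuple(f"P{i:03d}" for i in range(config.n_pairs))
    return PairedCounts(genes, pairs, tumor, normal), logfc


def simulate_ct_table(
    relative_expression: Mapping[str, float],
    seed: int | None = None,
    ct_ref: float = 20.0,
    ct_target_normal: float = 26.0,
    noise_sd: float = 0.15,
) -> pd.DataFrame:
    """qPCR Ct quadruples whose 2^-ddCt recovers the given relative expression."""
    rng = np.random.default_rng(seed)
    rows = []
    for tissue, rel in relative_expression.items():
        if rel <= 0:
            raise ValidationError(f"{tissue}: relative expression must be > 0")
        rows.append({
            "tissue": tissue,
            "ct_target_tumor": ct_target_normal - np.log2(rel) + rng.normal(0, noise_sd),
            "ct_ref_tumor": ct_ref + rng.normal(0, noise_sd),
            "ct_target_normal": ct_target_normal + rng.normal(0, noise_sd),
            "ct_ref_normal": ct_ref + rng.normal(0, noise_sd),
            "true_relative_expression": rel,
        })
    return pd.DataFrame(rows)


# --- bundled synthetic protein models ---------------------------------------

_PR = DomainKind.PR
_ZF = DomainKind.ZNF

_GENE_LAYOUT: dict[str, tuple[int, int | None, int]] = {
    # gene -> (length_aa, PR start (None for the FOG genes), n zinc fingers)
    "PRDM1": (789, 38, 5), "PRDM2": (1718, 29, 8), "MECOM": (1230, 15, 10),
    "PRDM4": (801, 296, 6), "PRDM5": (630, 9, 8), "PRDM6": (595, 100, 4),
    "PRDM7": (492, 182, 3), "PRDM8": (689, 54, 5), "PRDM9": (894, 244, 13),
    "PRDM10": (1129, 191, 9), "PRDM11": (563, 58, 0), "PRDM12": (367, 105, 3),
    "PRDM13": (754, 68, 4), "PRDM14": (571, 295, 6), "PRDM15": (1507, 59, 10),
    "PRDM16": (1276, 25, 10), "ZNF408": (720, 61, 8),
    "ZFPM1": (1006, None, 9), "ZFPM2": (1151, None, 8),
}

PR_DOMAIN_LEN = 120
ZNF_LEN = 23


def default_protein_models() -> dict[str, ProteinModel]:
    """Synthetic canonical-protein models for the 19 PRDM-family genes.

    Lengths are realistic for the family; domain coordinates are a
    plausible synthetic layout (one ~120-aa PR domain, evenly spaced
    23-aa zinc fingers downstream of it), intended for simulation and
    testing rather than as curated annotation.
    """
    models: dict[str, ProteinModel] = {}
    for gene, (length, pr_start, n_znf) in _GENE_LAYOUT.items():
        domains: list[DomainInterval] = []
        zf_region_start = 1
        if pr_start is not None:
            pr_end = pr_start + PR_DOMAIN_LEN - 1
            domains.append(DomainInterval("PR", _PR, pr_start, pr_end))
            zf_region_start = pr_end + 40
        if n_znf > 0:
            span = length - 10 - zf_region_start
            step = max(ZNF_LEN + 5, span // max(n_znf, 1))
            for k in range(n_znf):
                start = zf_region_start + k * step
                end = start + ZNF_LEN - 1
                if end > length:
                    break
                domains.append(DomainInterval(f"ZnF{k + 1}", _ZF, start, end))
        models[gene] = ProteinModel(gene, length, tuple(domains))
    return models


def acc_like_config(seed: int | None = None) -> MutSimConfig:
    """The default end-to-end fixture: an adrenocortical-like cohort pattern.

    92 ACC-like patients in which about half carry a ZFPM1 mutation inside
    a 4-residue window (444-447), half of those multi-hit, plus three
    smaller cohorts where the same window recurs at a lower rate, on top
    of a sparse pan-gene background.
    """
    models = default_protein_models()
    window = (444, 447)
    return MutSimConfig(
        cohorts=(("ACC", 92), ("COAD", 150), ("READ", 80), ("UCS", 57)),
        genes=tuple(models[g] for g in PRDM_GENES),
        background_rate=0.01,
        hotspots=(
            PlantedHotspot("ZFPM1", "ACC", window, 0.5),
            PlantedHotspot("ZFPM1", "COAD", window, 0.10),
            PlantedHotspot("ZFPM1", "READ", window, 0.12),
            PlantedHotspot("ZFPM1", "UCS", window, 0.08),
        ),
        enrichments=(PlantedEnrichment("PRDM9", 3.0),),
        multi_hit_rate=0.5,
        seed=seed,
    )


def default_expr_config(seed: int | None = None) -> ExprSimConfig:
    """Paired-expression fixture over the 19 family genes, 20 pairs.

    A handful of genes carry planted fold changes shaped like the
    pan-cancer expression pattern the pipeline is meant to surface:
    strong overexpression of PRDM12/PRDM13, downregulation of
    PRDM16/ZFPM2; the rest are null.
    """
    planted = {"PRDM12": 3.0, "PRDM13": 2.0, "PRDM16": -1.5, "ZFPM2": -2.0}
    logfc = tuple(float(planted.get(g, 0.0)) for g in PRDM_GENES)
    return ExprSimConfig(
        n_genes=len(PRDM_GENES),
        n_pairs=20,
        baseline_mean=100.0,
        dispersion=0.1,
        logfc=logfc,
        gene_names=PRDM_GENES,
        seed=seed,
    )


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
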