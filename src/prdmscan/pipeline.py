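"""End-to-end orchestration: one config in, a per-cohort report bundle out.

Every stage writes plot-ready TSV tables into the output directory, and a
``manifest.json`` records the package version, seed, thresholds and
enabled stages.  For a fixed config and seed the bundle is byte-for-byte
deterministic (the manifest carries no timestamps).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .consequence import deleterious_summary
from .drivers import driver_scan
from .enrichment import enrichment_table, map_to_domains, NO_DOMAIN
from .exceptions import ConfigurationError, PrdmscanError
from .expression import paired_de, read_paired_counts
from .landscape import (
    any_mutated_fraction,
    multi_hit_summary,
    mutation_class_counts,
    oncostrip_long,
    oncostrip_matrix,
    patient_frequency_matrix,
)
from .maf import (
    NONSYNONYMOUS_CLASSES,
    PRDM_GENES,
    MutationRecord,
    ProteinModel,
    dedupe_records,
    read_cohort_catalog,
    read_domain_table,
    read_maf,
    subset_records,
)
from .recurrence import cohort_hotspots, lollipop_table, recurrent_mutations
from .simulate import (
    ExprSimConfig,
    MutSimConfig,
    default_protein_models,
    simulate_maf,
    simulate_paired_counts,
    write_truth,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("landscape", "consequence", "enrich", "recurrence", "drivers", "de")


class PipelineStageError(PrdmscanError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass(frozen=True)
class PipelineConfig:
    # exactly one of (maf_paths + catalog) or mut_sim per the mutation side;
    # exactly one of counts paths or expr_sim per the expression side
    maf_paths: Mapping[str, str] | None = None        # cohort -> MAF path
    catalog_path: str | None = None
    domain_table_path: str | None = None              # default: bundled synthetic models
    counts_tumor_path: str | None = None
    counts_normal_path: str | None = None
    mut_sim: MutSimConfig | None = None
    expr_sim: ExprSimConfig | None = None
    gene_universe: tuple[str, ...] = PRDM_GENES
    stages: tuple[str, ...] = ALL_STAGES
    enrichment_alpha: float = 0.005
    enrichment_iterations: int = 1000
    de_logfc_threshold: float = 1.0
    de_fdr_threshold: float = 0.01
    hotspot_min_patients: int = 3
    recurrence_min_cohorts: int = 4
    driver_min_mutations: int = 5
    seed: int | None = None
    outdir: str = "prdmscan_out"

    def validate(self) -> None:
        if (self.maf_paths is None) == (self.mut_sim is None):
            raise ConfigurationError(
                "exactly one of maf_paths or mut_sim must be provided"
            )
        if self.maf_paths is not None and self.catalog_path is None:
            raise ConfigurationError("maf_paths requires catalog_path")
        has_counts = self.counts_tumor_path is not None
        if "de" in self.stages and has_counts == (self.expr_sim is not None) and not has_counts:
            raise ConfigurationError(
                "the de stage needs either counts paths or expr_sim"
            )
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")


def _stage_seed(root: np.random.SeedSequence, k: int) -> int:
    return int(root.spawn(k + 1)[k].generate_state(1)[0] & 0x7FFFFFFF)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the enabled stages and return a name -> written-path mapping."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root_ss = np.random.SeedSequence(config.seed)
    outputs: dict[str, Path] = {}

    def write(name: str, df: pd.DataFrame, index: bool = True) -> None:
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=index)
        outputs[name] = path

    # ---- inputs -------------------------------------------------------
    try:
        if config.mut_sim is not None:
            sim_cfg = dataclasses.replace(
                config.mut_sim,
                seed=config.mut_sim.seed if config.mut_sim.seed is not None
                else _stage_seed(root_ss, 0),
            )
            records, truth = simulate_maf(sim_cfg)
            write_truth(truth, outdir / "truth.json")
            outputs["truth"] = outdir / "truth.json"
            catalog = {c: n for c, n in sim_cfg.cohorts}
            models = {g.gene_symbol: g for g in sim_cfg.genes}
        else:
            records = []
            for cohort, path in sorted(config.maf_paths.items()):
                records.extend(read_maf(path, cohort))
            catalog = read_cohort_catalog(config.catalog_path)
            models = (
                read_domain_table(config.domain_table_path)
                if config.domain_table_path
                else default_protein_models()
            )
        if config.domain_table_path and config.mut_sim is not None:
            models = read_domain_table(config.domain_table_path)
        records = dedupe_records(subset_records(records, genes=config.gene_universe))
        cohorts = sorted(catalog)
    except PrdmscanError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineStageError("input", exc)

    by_gene: dict[str, list[MutationRecord]] = {g: [] for g in config.gene_universe}
    for r in records:
        by_gene.setdefault(r.gene_symbol, []).append(r)

    # ---- landscape ----------------------------------------------------
    if "landscape" in config.stages:
        try:
            write("class_counts", mutation_class_counts(records, config.gene_universe))
            write("frequency_matrix",
                  patient_frequency_matrix(records, catalog,
                                           gene_universe=config.gene_universe))
            rows = [
                {"cohort": c, "n_patients": catalog[c],
                 "pct_any_mutated": any_mutated_fraction(
                     records, c, catalog[c], config.gene_universe)}
                for c in cohorts
            ]
            write("any_mutated", pd.DataFrame(rows), index=False)
            mh_rows = []
            for c in cohorts:
                for g in config.gene_universe:
                    n_multi, n_mut, pct = multi_hit_summary(records, g, c)
                    if n_mut > 0:
                        mh_rows.append({"cohort": c, "gene_symbol": g,
                                        "n_multi_hit": n_multi, "n_mutated": n_mut,
                                        "pct_multi_hit": pct})
            write("multi_hit", pd.DataFrame(
                mh_rows, columns=["cohort", "gene_symbol", "n_multi_hit",
                                  "n_mutated", "pct_multi_hit"]), index=False)
            strips = []
            for c in cohorts:
                strip = oncostrip_long(
                    oncostrip_matrix(records, c, config.gene_universe))
                strip.insert(0, "cohort", c)
                strips.append(strip)
            write("oncostrip", pd.concat(strips, ignore_index=True)
                  if strips else pd.DataFrame(
                      columns=["cohort", "patient_id", "gene_symbol", "label"]),
                  index=False)
        except Exception as exc:
            raise PipelineStageError("landscape", exc)

    # ---- consequence --------------------------------------------------
    if "consequence" in config.stages:
        try:
            write("deleterious_summary",
                  deleterious_summary(records, config.gene_universe))
        except Exception as exc:
            raise PipelineStageError("consequence", exc)

    # ---- domain enrichment -------------------------------------------
    if "enrich" in config.stages:
        try:
            from .enrichment import deleterious_missense

            rows = []
            for g in config.gene_universe:
                if g not in models:
                    continue
                buckets = map_to_domains(deleterious_missense(by_gene.get(g, [])),
                                         models[g])
                rows.append({"gene_symbol": g, **buckets})
            write("domain_counts", pd.DataFrame(
                rows, columns=["gene_symbol", "PR", "ZnF", "OTHER", NO_DOMAIN]),
                index=False)
            table = enrichment_table(
                by_gene, models,
                iterations=config.enrichment_iterations,
                seed=_stage_seed(root_ss, 1),
            )
            table["significant"] = table["p_value"] < config.enrichment_alpha
            write("enrichment", table, index=False)
        except Exception as exc:
            raise PipelineStageError("enrich", exc)

    # ---- recurrence & hotspots ---------------------------------------
    if "recurrence" in config.stages:
        try:
            rec = recurrent_mutations(records, config.recurrence_min_cohorts)
            write("recurrence", pd.DataFrame(
                [{"gene_symbol": m.gene_symbol, "label": m.label,
                  "protein_position": m.protein_position,
                  "n_cohorts": m.n_cohorts,
                  "cohorts": ",".join(sorted(m.cohorts)),
                  "n_patients_total": m.n_patients_total} for m in rec],
                columns=["gene_symbol", "label", "protein_position",
                         "n_cohorts", "cohorts", "n_patients_total"]),
                index=False)
            hs_rows = []
            for c in cohorts:
                for h in cohort_hotspots(records, c, config.hotspot_min_patients):
                    hs_rows.append({
                        "cohort": c, "gene_symbol": h.gene_symbol,
                        "protein_position": h.protein_position,
                        "n_patients": h.n_patients,
                        "aa_changes": ",".join(sorted(h.aa_changes)),
                    })
            write("hotspots", pd.DataFrame(
                hs_rows, columns=["cohort", "gene_symbol", "protein_position",
                                  "n_patients", "aa_changes"]), index=False)
            lolli = []
            for g in config.gene_universe:
                if g not in models:
                    continue
                tab = lollipop_table(by_gene.get(g, []), g, models[g])
                if not tab.empty:
                    tab.insert(0, "gene_symbol", g)
                    lolli.append(tab)
            write("lollipop", pd.concat(lolli, ignore_index=True)
                  if lolli else pd.DataFrame(
                      columns=["gene_symbol", "protein_position", "count",
                               "domain", "domain_kind", "out_of_bounds"]),
                  index=False)
        except Exception as exc:
            raise PipelineStageError("recurrence", exc)

    # ---- driver scan --------------------------------------------------
    if "drivers" in config.stages:
        try:
            scans = []
            for k, c in enumerate(cohorts):
                sub = [r for r in records if r.cohort == c]
                if not any(
                    r.variant_class in NONSYNONYMOUS_CLASSES
                    and r.protein_position is not None for r in sub
                ):
                    continue
                df = driver_scan(
                    sub, models, seed=_stage_seed(root_ss, 2 + k),
                    min_mutations=config.driver_min_mutations,
                )
                if not df.empty:
                    df.insert(0, "cohort", c)
                    scans.append(df)
            scan_df = pd.concat(scans, ignore_index=True) if scans else pd.DataFrame(
                columns=["cohort", "gene_symbol", "n_mutations", "n_clusters",
                         "gene_score", "z_score", "p_value", "fdr"])
            write("driver_scan", scan_df, index=False)
            scatter = scan_df[["cohort", "gene_symbol", "gene_score", "fdr"]].copy()
            if not scatter.empty:
                scatter["neg_log10_fdr"] = -np.log10(scatter["fdr"])
            else:
                scatter["neg_log10_fdr"] = pd.Series(dtype=float)
            write("driver_scatter", scatter, index=False)
        except Exception as exc:
            raise PipelineStageError("drivers", exc)

    # ---- paired differential expression ------------------------------
    if "de" in config.stages:
        try:
            if config.expr_sim is not None:
                expr_cfg = dataclasses.replace(
                    config.expr_sim,
                    seed=config.expr_sim.seed if config.expr_sim.seed is not None
                    else _stage_seed(root_ss, 40),
                )
                paired, true_logfc = simulate_paired_counts(expr_cfg)
            elif config.counts_tumor_path is not None:
                paired = read_paired_counts(
                    config.counts_tumor_path, config.counts_normal_path)
                true_logfc = None
            else:
                paired = None
            if paired is not None:
                de = paired_de(
                    paired, seed=_stage_seed(root_ss, 41),
                    logfc_threshold=config.de_logfc_threshold,
                    fdr_threshold=config.de_fdr_threshold,
                )
                if true_logfc is not None:
                    de["true_logFC"] = true_logfc
                write("de_results", de, index=False)
        except Exception as exc:
            raise PipelineStageError("de", exc)

    # ---- manifest -----------------------------------------------------
    manifest = {
        "package": "prdmscan",
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "gene_universe": list(config.gene_universe),
        "thresholds": {
            "enrichment_alpha": config.enrichment_alpha,
            "enrichment_iterations": config.enrichment_iterations,
            "de_logfc_threshold": config.de_logfc_threshold,
            "de_fdr_threshold": config.de_fdr_threshold,
            "hotspot_min_patients": config.hotspot_min_patients,
            "recurrence_min_cohorts": config.recurrence_min_cohorts,
            "driver_min_mutations": config.driver_min_mutations,
        },
        "outputs": sorted(p.name for p in outputs.values()),
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    outputs["manifest"] = manifest_path
    return outputs
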