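# prdmscan

Pan-cancer somatic-mutation and paired-expression analysis for the PRDM
transcription-factor family — the 19 PR/SET-domain genes (PRDM1–PRDM16,
ZNF408/PRDM17) plus the FOG zinc-finger genes ZFPM1 and ZFPM2. These genes
encode a conserved N-terminal PR (PRDI-BF1/RIZ1 homology) domain, a SET
subtype with potential methyltransferase activity, followed by zinc-finger
repeats; most express a PR-plus (tumor-suppressive) and a PR-minus
(oncogenic) isoform, which makes their mutational disruption and
transcriptional imbalance interesting across tumor types.

The package is aimed at cancer-genomics analysts who want the whole chain —
from MAF-dialect mutation tables to per-cohort report tables — as a tested,
reusable library rather than an ad-hoc notebook:

* **Landscape** — per-gene variant-class counts, cohort × gene patient
  frequency matrices (percent of patients with ≥ 1 non-synonymous
  mutation), any-mutated fractions, multi-hit summaries, oncostrip-style
  label matrices.
* **Consequence** — deleterious vs tolerated classification: missense with
  SIFT ∈ [0, 0.05] and/or PolyPhen ∈ [0.5, 1], plus category-deleterious
  classes (frameshift, in-frame indel, stop-gained/lost, start-lost,
  splice-site, UTR, intron).
* **Recurrence** — lesions recurring across ≥ 4 tumor types, per-cohort
  hotspot positions, lollipop-plot tables with domain labels.
* **Domain enrichment** — a resampling test of whether deleterious missense
  mutations concentrate in the PR domain: 1000 iterations of size-weighted
  random placement (region probability ∝ region length), one-sided add-one
  p-value
  `p = (1 + #{null ≥ observed}) / (1 + iterations)`.
* **Driver scan** — OncodriveCLUST-style positional clustering: per-gene
  cluster scores (fraction of mutations in clusters) compared against a
  synonymous or simulated flat background; gamma-tail p-values, BH FDR.
* **Paired DE** — tumor vs matched-normal differential expression via an
  exact sign-flip permutation test on per-pair log2 CPM ratios, with the
  conventional |logFC| ≥ 1 and FDR ≤ 0.01 calls, and 2^−ΔΔCt for qPCR
  validation data.
* **Synthetic data** — cohort/MAF and paired-count simulators with planted
  hotspots, PR-domain enrichment, multi-hit rates and fold changes, so
  every stage is testable without any TCGA download.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Run the bundled ACC-like synthetic fixture (92 adrenocortical-like
patients, about half carrying a ZFPM1 mutation in the 4-residue window
444–447, half of those multi-hit, the same window recurring in three
smaller cohorts) end to end:

```python
from prdmscan.pipeline import PipelineConfig, run_pipeline
from prdmscan.simulate import acc_like_config, default_expr_config

config = PipelineConfig(
    mut_sim=acc_like_config(), expr_sim=default_expr_config(),
    seed=42, outdir="out",
)
outputs = run_pipeline(config)   # name -> path of every written table
```

or equivalently from the shell: `prdmscan all --seed 42 --out out`.

With seed 42 the bundle shows (actual printed values):

* `frequency_matrix.tsv` — ZFPM1 mutated in **56.5%** of ACC patients,
  against a 0–4% background for most other family members;
* `any_mutated.tsv` — **61.96%** of ACC patients carry ≥ 1 mutated family
  gene, versus 22–28% in the smaller cohorts;
* `multi_hit.tsv` — 30 of 52 ZFPM1-mutated ACC patients (**58%**) are
  multi-hit, the planted tumor-suppressor-like pattern;
* `hotspots.tsv` — the four planted window positions 444–447 appear as the
  top ACC hotspots (23, 22, 19 and 15 patients);
* `driver_scan.tsv` — ZFPM1 is the top ACC driver call: one cluster
  containing 98.8% of its 82 positioned mutations, FDR ≈ 7.8 × 10⁻¹⁰;
* `de_results.tsv` — the four planted expression changes are the four
  significant calls: PRDM12 (logFC 2.66, FC 6.3, UP), PRDM13 (1.13, UP),
  PRDM16 (−2.39, DOWN), ZFPM2 (−2.52, DOWN), all FDR ≈ 6 × 10⁻⁴.

Real MAF input works the same way through `PipelineConfig(maf_paths=...,
catalog_path=..., domain_table_path=...)` or the CLI's repeated
`--maf COHORT PATH` option.

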