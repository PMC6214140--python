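# Methods

`prdmscan` implements a desk-scale, fully testable version of a pan-cancer
mutation-and-expression analysis of the 19-member PRDM transcription-factor
family (PRDM1–PRDM16, ZNF408/PRDM17 and the FOG genes ZFPM1/ZFPM2). This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic-data experiments do and do not demonstrate.

## Mutation landscape

Input is the TCGA MAF dialect: tab-separated, `#` comments, free column
order, gzip transparent. Patient identity is the first 12 barcode
characters; duplicate calls of the same lesion in the same patient
(same patient/gene/genomic position/alternate allele) are collapsed before
any patient-level counting, because frequency tables count patients, not
calls. Unknown `Variant_Classification` labels are kept as a catch-all
class excluded from every count, so foreign MAF dialects degrade softly
rather than aborting.

The *qualifying* (non-synonymous) set is the conventional protein-altering
list: missense, nonsense, nonstop, splice-site, frameshift and in-frame
indels, and start-lost. Percentages follow printed-table conventions:
frequency-matrix cells to one decimal, cohort any-mutated fractions to two
decimals, multi-hit percentages to the nearest integer — all half-up.
(With truncation instead of half-up, 10/11 renders 90 rather than 91; the
package uses half-up throughout.)

## Deleterious classification

A missense mutation is deleterious when SIFT ∈ [0, 0.05] and/or
PolyPhen ∈ [0.5, 1]; a single qualifying score suffices and a missing
score never disqualifies the other. Both interval endpoints are inclusive.
Frameshift, in-frame indel, stop-gained, start-lost, splice-site, UTR and
intron variants are deleterious by category. Two deliberate conventions,
both exposed as options:

* UTR/intron membership in the category list is biologically debatable but
  is the convention this pipeline standardises on
  (`CATEGORY_DELETERIOUS_CODING_ONLY` removes them).
* Stop-lost (nonstop) and in-frame insertions are treated like their
  listed neighbours (stop-gained, in-frame deletions): all are plainly
  protein-altering.

Unscored missense (no score at all) is a third class, `UNSCORED`, counted
on the tolerated side of summary percentages by default (the conservative
choice; a flag drops such records from the denominator instead).

## PR-domain enrichment test

Null model: each of a gene's deleterious missense mutations lands
independently and uniformly over the residues of the canonical protein, so
every region is hit with probability proportional to its length — a
size-weighted random placement. Each of `iterations` (default 1000)
iterations redraws all `n` positions (with replacement; sampling without
replacement is a documented alternative reading, not implemented because
independent placement is the only version consistent with per-mutation
counting). The one-sided p-value uses the add-one estimator
`p = (1 + #{null ≥ observed}) / (1 + iterations)`, which cannot return 0.
On a protein whose only annotated feature is a PR domain of relative
length *f*, the null PR count is exactly Binomial(n, f); the tests use
that closed form as the oracle. The default significance threshold is
0.005, uncorrected across genes.

Two properties of the discrete estimator matter for calibration studies:

* The attained size at nominal 0.05 is below 0.05 (roughly 0.04 in the
  continuous-n limit) because of the add-one correction and the
  integer-valued statistic. Calibration simulations therefore use genes
  with 150–400 mutations on 250–700-residue proteins with 100–140-residue
  PR domains, where the granularity is fine enough for the attained size
  to sit in the 3–7% window; with only 20–80 mutations per gene the same
  test runs at ~2–4% — conservative, never anti-conservative.
* Power: with a 3× relative deleterious-missense rate inside a PR domain
  occupying fraction f = 0.2 of the protein, the probability of a domain
  hit rises from 0.2 to 3f/(1+2f) = 0.43. An exact binomial calculation
  gives ≥ 90% power at p < 0.005 from about n = 70–80 mutations; the power
  simulations use n = 80 (realistic for heavily mutated family members,
  which carry several hundred calls pan-cancer). At n = 20 the same effect
  size has only ~40% power — a floor of the test's design, not of the
  implementation.

## Positional-clustering driver scan

Per gene, mutated protein positions are clustered: any position with at
least `max(2, ⌈1% of the gene's mutations⌉)` mutations seeds a cluster,
which extends over neighbouring mutated positions within a 5-residue gap
while the mean count over the cluster's positions stays ≥ 10% of the seed
count; overlapping clusters merge. The gene score is the fraction of the
gene's mutations inside clusters (≤ 1 by construction). These defaults
mirror the published OncodriveCLUST parameterisation.

The background is the synonymous (silent) mutation set processed
identically, one score per background gene; when fewer than 20 background
gene scores exist, the scan falls back (with a logged notice) to a
simulated background: each tested gene replicated with the same mutation
count placed uniformly over its protein, 200 replicates in total.

Significance: the background scores determine a mean and SD, reported as a
z-score per tested gene — but the p-value is the upper tail of a **gamma
distribution moment-matched to the background**, not of a standard normal.
Null gene scores are strongly right-skewed (approximately a scaled Poisson
in the number of chance position collisions); in flat-null simulations
(19 genes × 50 mutations) a normal upper tail false-flags at least one
gene at BH FDR < 0.05 in ~25–30% of scans, while the gamma tail, fitted
from exactly the same two background moments, flags essentially none and
still calls a planted hotspot gene (half the cohort mutated in a 4-residue
window) at FDR ≪ 0.05. Genes with fewer than 5 positioned mutations are
excluded; BH correction runs across the tested genes of one scan.

## Paired differential expression

Counts are CPM-normalised with a 0.5 pseudocount
(`1e6·(c+0.5)/(lib+G·0.5)`), keeping log-ratios finite at zero counts. Per
gene, the statistic is the paired t over per-pair log2 CPM ratios
r_i = log2(T_i/N_i). Under the no-effect null the r_i are symmetric about
zero, so sign-flipping is an exact permutation scheme: all 2^n flips are
enumerated when 2^n ≤ `n_permutations` (default 10 000), otherwise Monte
Carlo with add-one tails. Two-sided p doubles the smaller tail, capped at
1. Zero-variance genes report p = 1 with a flag. Calls use |logFC| ≥ 1 and
BH FDR ≤ 0.01.

Granularity note: with n pairs the smallest attainable two-sided p is
2/2^n, so with 10 pairs the post-BH floor is 0.00195·m/rank — the
FDR ≤ 0.01 call is reachable only for panels of ≤ 5 genes at rank 1.
Recovery experiments that assert on *calls* therefore use small panels or
≥ 13 pairs; experiments that assert on the logFC *estimate* are
unaffected.

This sign-flip test deliberately replaces the negative-binomial GLM used
in large reprocessing pipelines: it is self-contained, exactly calibrated
under symmetry, and validated here by calibration and parameter-recovery
simulation rather than numeric identity with any external fit. The cost is
somewhat lower power at very small n and no shrinkage across genes.

qPCR relative expression is the comparative-Ct method, 2^−ΔΔCt with
ΔΔCt = (Ct_target − Ct_ref)_tumor − (Ct_target − Ct_ref)_normal; a
non-finite Ct (undetectable amplification) is a validation error rather
than a silent zero.

## Synthetic data

The mutation simulator emulates the structure of TCGA cohort MAFs:
per-cohort barcodes, per-patient-per-gene Poisson background (default
0.01 mutations per patient-gene), a variant-class mixture shaped like
pan-cancer exome calls (~27% silent, missense dominating, indels rare),
SIFT/PolyPhen scores drawn inside the deleterious intervals for planted
damaging missense and outside them otherwise. Planted events — hotspots
(gene, cohort, window, patient fraction, multi-hit rate) and PR-domain
enrichment (relative rate inside the domain) — are returned in a truth
table. The default end-to-end fixture is "ACC-like": 92 patients with
~50% carrying a ZFPM1 mutation in a 4-residue window (444–447), half of
those multi-hit, the same window recurring at low rates in three further
cohorts.

The expression simulator draws NB(mean·2^logFC·lib, dispersion) tumor and
NB(mean·lib, dispersion) normal counts per pair, with lognormal
library-size factors (σ = 0.2) and dispersion 0.1 — typical bulk RNA-seq
values.

The bundled protein models (lengths, one ~120-aa PR domain, evenly spaced
zinc fingers, none for the FOG genes) are synthetic plausible layouts, not
curated annotation. What the simulator does **not** model: trinucleotide
mutational signatures, transcript structure, copy number, gene–gene
expression correlation, and batch effects. Passing tests therefore
demonstrate that the algorithms recover what they are defined to recover
under their stated null models — not that real TCGA cohorts would
reproduce any specific published value.

## Problem sizes

The validation suites use: 500 genes for each null-calibration study
(enrichment and DE), 100 simulations for each power/recovery study, 100
flat scans for driver-scan calibration, and 1000 resampling iterations per
enrichment test. These sizes give Monte-Carlo standard errors comfortably
inside the asserted tolerance bands while the full suite runs in seconds.

## Known limitations

* The enrichment test is per-gene and uncorrected across genes, matching
  its single-threshold (p < 0.005) usage; a family-wide screen should
  correct externally.
* The driver scan's gamma null is a two-moment approximation; extremely
  small backgrounds (< ~20 scores) make both moments noisy, which is why
  the simulated fallback inflates the background to 200 replicates.
* Recurrence identity for indel/splice events is gene + position + class;
  distinct indel alleles at one position are deliberately treated as one
  recurrent lesion.
* Whether Table-1-style denominators are patients or tumor samples is
  ambiguous in the source convention; this package counts patients (first
  12 barcode characters) throughout.
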