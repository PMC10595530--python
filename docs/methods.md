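# Methods

This note documents the models behind `ewstme`, the defaults and why
they were chosen, what the synthetic cohorts do and do not emulate, and
the numerical decisions that shape the results. Nothing here states an
empirical number that the test suite or `scripts/acceptance.py` does not
itself compute.

## The synthetic cohort model

The generator (`ewstme.synthetic`) emulates a plate-based multi-sample
single-cell study of a pediatric solid tumor at desk scale. Counts for
gene *g* in cell *c* are negative binomial (gamma–Poisson):

```
count_gc ~ NB(mean = d_c · μ_g · m_gc ,  dispersion φ)
Var = mean + φ·mean²,   φ = 0.3 by default
```

- `d_c` is a per-cell library-size factor, lognormal(0, 0.35) around a
  median depth of 5,000 UMIs/cell — a generic plate-based (CEL-Seq2-like)
  depth profile, since real per-sample depth distributions vary widely.
- `μ_g` is a lognormal(0, 1) baseline, normalized so per-cell totals hit
  the target depth. HLA class I genes get an elevated baseline (they are
  among the most abundant transcripts in real data), HLA class II,
  the inhibitory-receptor panel and ligand/receptor genes moderately so.
- `m_gc` multiplies in the planted biology: marker-program boosts (6×
  for a cell type's markers), copy-number fold changes (1.5× on arms
  1q/2q/8q in tumor cells by default), HLA-I downregulation (0.3× in
  tumor cells), receptor/ligand boosts in the axis source and target
  types, and the per-sample dysfunction shift on panel genes in CD8⁺
  T cells.
- A shared dispersion of 0.3 is typical UMI overdispersion and matches
  the variance structure that regression-based variance stabilization
  assumes.

Costimulatory genes (*CD70, CD80, CD83, CD86, TNFSF9*) are zero-inflated:
a Bernoulli switch per cell (probability configurable per cell type,
default 0.05 in Mo/Mφ/cDC for the sparse "sarcoma-like" regime, 0.4 for
an abundant "reference-like" cohort) gates an NB component with mean 2.5
counts. This makes the *percentage of expressing cells* directly
plantable, which is the statistic the fraction analysis measures.

The cohort defaults — 12 samples from 8 patients (many-to-one),
350–450 cells/sample, 2,000 genes, ten cell types spanning tumor,
endothelial, CAF and immune compartments, treatment status alternating
naive/exposed — are desk-scale stand-ins for a small clinical cohort.
Sample-to-sample composition varies via a Dirichlet draw (concentration
50) around the base proportions.

**The dysfunction axis.** Each planted ligand–receptor axis (default
NECTIN2 on macrophages → TIGIT on CD8⁺ T cells) carries per-sample
strength factors `s_j ~ lognormal(0, 0.5)` multiplying the ligand's mean
in source cells. `plant_dysfunction_axis` couples the CD8
inhibitory-receptor panel to the axis: panel means in CD8 cells of
sample *j* are scaled by `exp(α_j)` with

```
α_j = coupling · z(log s_j) + noise_sd · ε_j
```

With the defaults (coupling 0.5, noise 0.36) the population Pearson
correlation between log-strength and α is `0.5/√(0.25+0.36²) ≈ 0.81`,
i.e. a population Spearman of about 0.8 — a strong but not deterministic
coupling, which is what a screen needs to be tested against. With zero
noise the sample ranking by strength equals the ranking by expected
dysfunction exactly; with zero coupling all samples share one expected
value. One deliberate interaction: TIGIT is both the planted receptor
and a member of the dysfunction panel (it is an inhibitory receptor), so
estimated screen correlations tend to run somewhat above the planted
truth-level coupling.

**What the generator does not emulate:** doublets, ambient RNA,
batch/plate effects beyond library size, transcriptional bursting
beyond NB overdispersion, realistic gene–gene correlation structure, or
read-level artifacts. Passing tests therefore demonstrate that the
estimators recover their targets under the stated count model — not
that they are robust to every artifact of real data.

## Normalization

Two methods, tagged on the output matrix:

- `log1p_cp10k`: `x → log(1 + 10⁴·x/depth)` — the default, used by all
  scoring and the CNV module.
- `pearson_residual`: `(x − μ̂)/√(μ̂ + μ̂²/θ)` with
  `μ̂ = depth·gene_total/grand_total` and fixed θ = 100, clipped at
  ±√n_cells. This is the analytic (closed-form) approximation to
  regression-based NB variance stabilization: dependency-free, exact for
  depth-scaled profiles (residuals vanish), and adequate at desk scale.
  All-zero genes are defined to have residual 0.

## Module scores

The binned-control scheme: genes are ranked by mean expression into
`n_bins = 25` bins; for each signature gene, `n_ctrl = 100` control
genes are drawn without replacement from its bin (the whole bin if it is
smaller); the score is mean(signature) − mean(controls) per cell. The
control pool deliberately may include signature genes: with one bin and
the full pool the score then reduces *exactly* to mean(signature) minus
the grand mean, which is the identity the test suite checks. The control
draw is seeded and logged; random gene sets score zero on average
(checked to ±0.02).

The dysfunction score is a module score over the inhibitory-receptor
panel {LAG3, HAVCR2, TIGIT, PDCD1, CTLA4, BTLA, KLRG1, ENTPD1}. The
panel ships as an editable GMT entry: LAG3 and HAVCR2 (TIM-3) are the
anchor markers; the remainder is a documented default drawn from the
standard exhaustion literature, configurable per run. The same applies
to the antigen-presentation/costimulation set and the M1/M2 and
pro-/anti-inflammatory panels, which are clearly marked synthetic
stand-ins for study-specific supplementary lists.

"Expressing" always means raw count > 0 on unnormalized (optionally
depth-downsampled) counts. Sample/group combinations with fewer than 5
cells are omitted rather than reported as noisy fractions.

## Statistics

Two-group comparisons use the two-sided Wilcoxon rank-sum/Mann–Whitney U
test — exact enumeration for small groups (≤ 8 without ties via scipy's
exact path; the per-gene DE switches to the tie-corrected,
continuity-corrected normal approximation above 10 per group), Bonferroni
corrected across genes for DE. Three or more groups: Kruskal–Wallis with
Dunn's post hoc z-tests on pooled ranks (tie-corrected variance),
Bonferroni-adjusted across pairwise contrasts. Dunn's test is implemented
in-package (no maintained implementation exists in the environment); a
hand-computed three-group example pins the z statistics in the tests.
Significance uses the ≤ 0.05 rule, so p exactly at the threshold counts.

Null calibration of the rank-sum p-values (rejection rate at α = 0.05
over 10⁴ null genes at n = 20 per group) is part of the acceptance
suite.

## CNV inference

The estimator confirms malignant identity from expression alone. Per
gene, relative expression is the cell's linear CP10K value divided by a
per-gene reference level; windows of 101 genes (centered moving average,
ordered by genomic position, never crossing a chromosome-arm boundary)
are averaged on the linear scale and then log2-transformed; each cell is
centered at the genome-wide median of its per-arm means; values are
clipped at ±3.

Several choices here are deliberate and were driven by amplitude
fidelity — a planted 1.5× arm gain should read close to log2 1.5 ≈ 0.585:

- **Linear-scale smoothing before the log.** Taking logs per gene at
  single-cell counts (2–5 per gene) shrinks a 1.5× fold to roughly half
  its value through pseudocount and Jensen effects; averaging the ratio
  over the window first removes almost all of that shrinkage.
- **Reference level = median across reference cell-group means** (cell
  types or clusters), not the pooled mean. A marker gene of one
  reference population (e.g. *GZMA* in CD8 cells) otherwise inflates the
  pooled reference and drags down every window in its neighborhood for
  all query cells.
- **Winsorized ratios (cap 8).** Bounds the influence of a single
  highly expressed gene (e.g. a tumor marker) on its window; arm-level
  gains of ≤ 2× are far below the cap, so amplitude is unaffected.
- **Minimum reference expression (1 CP10K).** Genes barely detected in
  the reference carry almost no copy-number signal but dominate the
  window variance; dropping them is standard practice for
  expression-CNV smoothing.
- **Centering on the median of per-arm means** rather than the median
  over raw windows: marker programs and real focal signals shift many
  windows of a few arms; the median over ~46 arm summaries is robust to
  that, while the raw-window median is not.

Arm scores are per-cell means over an arm's windows; calls are
gain/neutral/loss at ±3 reference SDs around the reference mean.
Known limitations: strong transcriptional programs confined to one arm
can mimic CNV (HLA-I downregulation on 6p genuinely shows as a negative
arm signal — in this application that is itself a tumor feature);
amplitude is shrunk for folds far above the winsor cap; the method is
arm-level by construction and does not segment breakpoints.

## Cell–cell communication

The mass-action Hill form: `P = (L·R)ⁿ/(Khⁿ + (L·R)ⁿ)` with `L`, `R`
10%-trimmed means of normalized expression in the source and target
groups, geometric-mean aggregation over complex subunits (a missing
subunit zeroes the complex), `Kh = 0.5`, `n = 1`. This is the core of
the established communication-probability framework without its
cofactor and agonist/antagonist layers — a documented simplification;
the trimmed mean replaces truncated-mean-with-minimum-fraction because
it is robust, simple and directly testable. Significance is by label
permutation: `p = (1 + #{P_perm ≥ P_obs})/(n_perm + 1)`; an observed
probability of exactly zero is reported with p = 1 (nothing to exceed).
Uniformity of the null p-values is part of the acceptance suite.

The packaged pair database stores canonical ligand→receptor orientation
with a display field for conventional (sometimes receptor-first) names,
and covers the immunoregulatory pairs central to this domain
(NECTIN2–TIGIT, SELPLG–SELL, SPN–SIGLEC1, CD47–SIRPA, GAS6–AXL,
TNFSF10–TNFRSF10B, RPS19–C5AR1, VEGFA–NRP1/2, SPP1–CD44, MDK–LRP1,
SEMA3A/4D axes, ANXA1–FPR1/2/3, WNT5A–FZD2, TGFB1 pairs, IGF1–IGF1R,
LGALS9–HAVCR2).

## The dysfunction screen

Strengths are computed within each sample independently (no information
shared across samples): trimmed-mean expression per myeloid source
subset and the CD8 target, Hill probability per (source, pair), then
aggregated to pair level by the maximum over source subsets (a pair's
strength is its strongest myeloid signal; mean aggregation is available).
A (sample, pair) entry is missing — never zero — when either group has
fewer than 5 cells in that sample, consistent with the fraction
exclusion rule. Per-sample dysfunction is the mean module score over the
sample's CD8⁺ T cells (median available).

Selection: Spearman correlation (rank-based, consistent with the
package's nonparametric statistics; Pearson available) between a pair's
strength column and the dysfunction vector, pairwise-complete, one-sided
— positive correlations above 0.5 with at least 3 samples. Zero-variance
columns are flagged not-evaluable and never selected. No
multiple-testing correction is applied by default; a Benjamini–Hochberg
flag exists as an extension. The acceptance suite measures both the
planted-pair selection rate and the decoy false-selection rate over 200
replicate cohorts, and a separate test checks the null selection rate
against an independent permutation oracle.

## Preranked GSEA

Classic weighted KS running sum (weight 1): hits add
`|stat|^w / Σ_hits|stat|^w`, misses subtract `1/(N − N_h)`; ES is the
walk extremum. The null permutes gene labels — appropriate because the
input is a preranked DE list with no phenotype labels left to permute.
`NES = ES / mean(|ES_perm| of the same sign)`;
`p = (1 + #{same-sign |ES_perm| ≥ |ES|})/(n_same + 1)`. Ties in the
ranking break by symbol for determinism. A brute-force walk oracle pins
the ES exactly on short lists.

## Orchestration and reproducibility

The pipeline runs QC → normalize → cluster → annotate → CNV →
signatures/fractions → interactions → screen → GSEA, writing UTF-8 TSVs
(6 significant digits), a JSON-lines run log (parameters, seeds,
versions) and a summary report. The master seed is split into named
substreams (CRC32 of the stage name into a seed sequence), so changing
one stage's parameters never perturbs another stage's draws, and two
runs with one seed are byte-identical. Louvain clustering runs on a kNN
graph (k = 15) of the top 30 PCs at resolution 1.0 — defaults chosen as
field-standard values, since no single best setting exists; the
community detection consumes a seeded RNG for determinism.

QC defaults (100 genes/cell minimum in the pipeline, samples dropped
below 20 surviving cells) are configurable and logged; the sample
threshold reflects that a sample sequenced to only a handful of usable
cells cannot support per-sample statistics. Clustering operates on the
pooled cohort without batch integration — the generator plants no batch
effects beyond depth, and integration is out of scope.

## Problem sizes

Validation runs use desk-scale cohorts chosen to make the planted
effects estimable with comfortable margins: full-structure cohorts of
6–12 samples × 150–450 cells at 1,200–2,000 genes for HLA/CNV/fraction
recovery; 200 replicate cohorts of 12 samples × ~110 cells × 300 genes
for the screen's operating characteristics; 10⁴ null genes for test
calibration; 1,000 permutations for communication and GSEA p-values.
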