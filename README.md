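# ewstme

Single-cell analysis toolkit for the Ewing sarcoma tumor immune
microenvironment.

Ewing sarcoma is an aggressive pediatric bone and soft-tissue tumor with
low mutational burden and, consequently, low immunogenicity. Dissecting
its microenvironment from single-cell RNA-seq means answering a chain of
quantitative questions: which cells are malignant (confirmed by
expression-inferred copy-number gains and low HLA class I), how
dysfunctional the infiltrating T/NK cells are (inhibitory-receptor
scores), whether the antigen-presenting compartment can costimulate T
cells at all (fractions of cells expressing *CD70/CD80/CD83/CD86/TNFSF9*),
and which tumor- or myeloid-derived ligand–receptor signals track the
CD8⁺ T-cell dysfunction gradient across samples. `ewstme` implements
that chain as a tested, reusable pipeline, together with a synthetic
cohort generator that plants every one of these structures with known
ground truth so the whole analysis can be validated end to end.

## What is implemented

- **Synthetic cohorts** (`ewstme.synthetic`) — multi-sample, multi-patient
  negative-binomial UMI counts with cell-type marker programs, tumor-restricted
  arm-level copy-number gains, HLA-I downregulation, zero-inflated
  costimulatory genes with plantable expressing-probabilities, and
  per-sample ligand–receptor axes coupled to CD8 dysfunction. All latent
  draws are recorded in a `SimTruth` oracle.
- **Preprocessing** (`ewstme.preprocess`) — QC filtering, `log1p` CP10K or
  analytic Pearson-residual normalization, PCA/kNN Louvain clustering,
  marker-based cluster annotation, per-gene Wilcoxon rank-sum DE with
  Bonferroni correction, and exact-depth (multivariate hypergeometric)
  downsampling.
- **Signature scores** (`ewstme.signatures`) — binned-control module scores

  `score(cell) = mean(expr, signature) − mean(expr, expression-matched controls)`,

  z-score signatures, dysfunction scores over an inhibitory-receptor panel
  (*LAG3, HAVCR2, TIGIT, PDCD1, CTLA4, BTLA, KLRG1, ENTPD1*), per-sample
  expressing fractions, and the study's group tests (Wilcoxon/Mann–Whitney,
  Kruskal–Wallis with Dunn post hoc).
- **CNV inference** (`ewstme.cnv`) — positionally smoothed log2 relative
  expression against a non-malignant reference, arm scores and
  gain/neutral/loss calls.
- **Cell–cell communication** (`ewstme.interactions`) — mass-action Hill
  model: for ligand mean `L` in the source group and receptor mean `R` in
  the target group,

  `P = (L·R)^n / (Kh^n + (L·R)^n)`

  with multi-subunit complexes aggregated by geometric mean, and
  label-permutation p-values. A curated database of immunoregulatory
  pairs (NECTIN2–TIGIT, GAS6–AXL, CD47–SIRPA, …) ships with the package.
- **Dysfunction screen** (`ewstme.screen`) — per-sample communication
  strengths (myeloid subsets → CD8⁺ T) correlated with per-sample mean
  CD8 dysfunction scores; pairs with Spearman ρ > 0.5 are selected.
- **Preranked GSEA** (`ewstme.gsea`) — weighted Kolmogorov–Smirnov
  enrichment scores with gene-permutation NES and p-values.
- **Orchestration** (`ewstme.pipeline`) — a config-driven end-to-end run
  with per-stage TSV outputs, a JSON-lines log and a summary report,
  reproducible from a single master seed.

## Worked example

```python
import scipy.stats as st
from ewstme import SimConfig, simulate_cohort, SignatureSet, module_score
from ewstme.signatures import HLA_CLASS_I, dysfunction_score
from ewstme.preprocess import normalize
from ewstme.interactions import default_lr_database
from ewstme.screen import per_sample_strengths, sample_dysfunction, screen

cfg = SimConfig(seed=1, n_samples=12, n_patients=8,
                cells_per_sample=(150, 200), n_genes=1200)
counts, cells, genes, truth = simulate_cohort(cfg)
print(f"cohort: {counts.shape[0]} genes x {counts.shape[1]} cells, "
      f"{cells['sample_id'].nunique()} samples")
norm = normalize(counts)

hla = module_score(norm, SignatureSet("hla_class_i", HLA_CLASS_I), seed=1)
tumor = (cells["cell_type"] == "tumor").to_numpy()
u = st.mannwhitneyu(hla[tumor], hla[~tumor], alternative="less")
print(f"HLA-I module score: tumor {hla[tumor].mean():.2f} vs "
      f"non-tumor {hla[~tumor].mean():.2f}, rank-sum p "
      f"{'< 1e-300' if u.pvalue < 1e-300 else f'= {u.pvalue:.2e}'}")

db = default_lr_database()
strengths = per_sample_strengths(norm, cells, db, ["Mo", "Mphi", "cDC"], "CD8_T")
dys = sample_dysfunction(dysfunction_score(norm, seed=1), cells)
result = screen(strengths, dys, rho_threshold=0.5)
print("selected dysfunction-correlated interactions:")
print(result[result["selected"]][["pair_id", "rho", "n"]].round(3).to_string(index=False))
```

Output:

```
cohort: 1200 genes x 2079 cells, 12 samples
HLA-I module score: tumor -0.09 vs non-tumor 1.14, rank-sum p < 1e-300
selected dysfunction-correlated interactions:
      pair_id   rho  n
NECTIN2_TIGIT 0.972 12
   WNT5A_FZD2 0.552 12
```

The tumor cells' HLA class I module score sits far below the rest of the
cohort (the generator plants a 0.3× downregulation), and the screen
recovers the planted NECTIN2→TIGIT macrophage→CD8 axis as the top
dysfunction-correlated interaction at ρ = 0.97 across the 12 samples;
WNT5A–FZD2 is a decoy that crossed the 0.5 threshold by chance in this
cohort — at 12 samples the null probability of a decoy exceeding ρ = 0.5
is about 5%.

The same analyses are available from the shell:

```bash
ewstme simulate --out cohort/ --seed 1
ewstme run --config pipeline.yaml      # full pipeline + report
```

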