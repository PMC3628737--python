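# gutlipid

Integrated analysis of paired gut-microbiota and serum-lipidomics profiles
from intervention cohorts. The package is aimed at microbiome researchers who
have genus-level abundance tables (log10 signal scale), lipid species
intensity tables (named as `CLASS(C:D)`, e.g. `TG(54:5)`), per-sample
metadata (subject, time point, treatment arm) and optionally an enzymatic
lipid panel (TC/LDL/HDL/TG), and who want to answer two questions: *did the
intervention change anything?* and *which microbes co-vary with which serum
lipids?*

## What it computes

- **Profile stability.** Intra-individual stability (Pearson r of a
  subject's log10 profile across time points) and inter-individual
  similarity (mean pairwise r between subjects at one time point), per
  treatment group, with Wilcoxon rank-sum group comparisons and PCA maps.
- **Moderated intervention tests.** Per-taxon contrasts on within-subject
  paired differences with empirical-Bayes variance moderation: the
  per-taxon variance s² is shrunk towards a pooled prior s0² with prior
  degrees of freedom d0 (estimated by moments of log s²), giving the
  moderated statistic t = β̂ / (s̃ √v) with s̃² = (d0 s0² + d s²)/(d0 + d)
  on d0 + d df, plus BH-adjusted p and Storey q-values. A permutation-based
  empirical power routine inserts fold-change alterations into permuted
  data and measures the detection rate of the full rule.
- **Robust correlation screen.** Biweight midcorrelation (median/MAD
  centring with Tukey biweight weights, tuning constant 9) between every
  taxon and every lipid over pooled observations; Student-t p-values;
  Storey q-values over the whole grid (π0 estimated with the smoother,
  reducing to Benjamini–Hochberg at π0 = 1); significant pairs at q < 0.05
  and |r| ≥ 0.5; two-way UPGMA-clustered correlation heatmap.
- **Plaid biclustering.** Constant plaid model
  Y_ij ≈ μ0 + Σ_k μ_k ρ_ik κ_jk fitted greedily on the correlation matrix,
  each layer accepted only if it beats the best layer fitted to each of S
  entry-permuted copies of the residuals (a permutation test at level
  1/(S+1); S = 39 by default).
- **Enrichment.** Fisher exact over-representation of lipid structural
  categories (odd/even carbons, SAFA/MUFA/PUFA, long chain, ether linkage
  — parsed from the nomenclature) and of taxonomic groups within
  biclusters.
- **Panel corroboration.** The identical bicor + q-value machinery applied
  to enzymatically determined TC/LDL/HDL/TG.
- **Synthetic cohorts.** A generator with subject-nested variance
  components, a planted intervention spike and planted taxon–lipid
  associations, plus a ground-truth ledger — so the entire pipeline runs
  and is testable with no external data. See `docs/methods.md` for the
  model and calibration.

## Worked example

```python
from gutlipid import simulate, stability, diffabund, correlate

design = simulate.CohortDesign(seed=42)   # 25 subjects, 131 taxa, 407 lipids
abundance, lipid, metadata, panel, truth = simulate.generate_cohort(design)

print(stability.stability_report(abundance, metadata).round(2))
#            between_tp1  between_tp2  between_tp3  within_tp1_vs_tp2 ...
# placebo           0.81         0.81         0.81               0.94
# probiotic         0.79         0.80         0.79               0.94

contrast = diffabund.fit_moderated_contrast(
    abundance, metadata, groups=("probiotic", "placebo"))
print(contrast.table[contrast.table.p_adjusted < 0.05].round(3))
#                                  effect_log10      t  moderated_t      p
# Lactobacillus rhamnosus et rel.         0.941  6.525         6.61    0.0

scr = correlate.screen(abundance, lipid, r_min=0.5, q_max=0.05)
print(scr.n_significant, "significant pairs over", len(scr.significant_taxa), "taxa")
# 35 significant pairs over 7 taxa
print(scr.pairs.head(3).round(3))
#                          taxon     lipid      r    p    q
#    Ruminococcus gnavus et rel.  TG(44:3)  0.784  0.0  0.0
#    Ruminococcus gnavus et rel.  TG(42:8)  0.759  0.0  0.0
#    Ruminococcus gnavus et rel.  TG(42:4)  0.754  0.0  0.0
```

Reading the output: within-subject microbiota correlations (~0.94) sit well
above between-subject ones (~0.80), the hallmark of a subject-specific gut
ecosystem; the only taxon moved by the intervention is the ingested
probiotic analogue (a +0.94 log10 transient spike); and the correlation
screen recovers the planted positive association between the
*R. gnavus*-like taxon and triglyceride species at r ≈ 0.6–0.8.

The same analysis is available as a CLI:

```bash
gutlipid simulate --seed 42 --out-dir cohort
gutlipid run-all --abundance cohort/abundance.tsv --lipids cohort/lipids.tsv \
    --metadata cohort/metadata.tsv --panel cohort/panel.tsv --out-dir results
```

(`gutlipid run-all` with no inputs generates the default synthetic cohort
itself.)

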