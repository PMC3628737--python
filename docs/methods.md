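# Methods

`gutlipid` implements an integrated analysis of paired gut-microbiota and
serum-lipidomics profiles from a two-arm probiotic intervention cohort:
profile-stability statistics, a moderated per-taxon intervention test with an
empirical power calculation, a robust taxon × lipid correlation screen with
q-value FDR control, constant plaid-model biclustering of the correlation
matrix, structural-category enrichment of lipids parsed from their
nomenclature, and a cross-platform check against an enzymatically determined
lipid panel. A synthetic cohort generator with a ground-truth ledger supplies
data with the statistical structure the analysis assumes, so the whole
pipeline runs and is testable without any external download.

## Synthetic cohort model

Each feature (genus-level taxon or lipid species) follows a Gaussian
variance-component model on the log10 scale:

    x[s, t, f] = baseline + m[f] + a[s, f] + e[s, t, f]

with feature effect `m ~ N(0, σ²_shared)` (common to all subjects), subject
effect `a ~ N(0, σ²_subject)` and observation noise `e ~ N(0, σ²_noise)`.
Writing `T = σ²_shared + σ²_subject + σ²_noise`, the expected profile
correlation across features is `σ²_shared / T` between two subjects
(inter-individual) and `(σ²_shared + σ²_subject) / T` within a subject across
time points (intra-individual). The defaults solve this two-equation system
for the target stability profile:

| omic       | σ²_shared | σ²_subject | σ²_noise | intra r | inter r |
|------------|-----------|------------|----------|---------|---------|
| microbiota | 0.77      | 0.17       | 0.06     | 0.94    | 0.77    |
| lipidome   | 0.90      | 0.02       | 0.08     | 0.92    | 0.90    |

reproducing the characteristic contrast between the subject-specific gut
ecosystem and the homeostatically controlled serum lipidome. The total
variance is normalised to 1 per feature; the baselines (3.0 log10 signal for
taxa, 5.0 log10 intensity for lipids) and the marginal scale are free
parameters of the simulation, not claims about any real platform. Values are
generated directly on the log10 scale and no compositional closure is
imposed, because every downstream statistic operates on log signals.

**Planted intervention effect.** One taxon (the ingested-probiotic analogue)
receives a +1.0 log10 (ten-fold) shift in the probiotic group at the second
time point only, emulating transient excretion of an ingested strain that is
clearly detectable against a within-subject noise SD of √0.06 ≈ 0.24.

**Planted taxon–lipid associations.** Each association adds one shared
latent `g ~ N(0, 1)` per (subject, time point) observation to a taxon column
and a set of lipid columns. Loadings are `λ = σ_f · sqrt(|ρ| / (1 − |ρ|))`
with `σ_f` the feature's per-observation SD, which makes the population
correlation of every planted pair exactly the target ρ (loadings are equal
after standardisation; scaling by `σ_f` is required because the two omics
have different per-observation variances). Defaults emulate a realistic
screen outcome: a clostridial taxon tied to 30 triglycerides at ρ = 0.61,
a second clostridial taxon tied to 4 TGs at ρ = 0.58, a Coriobacteriaceae
taxon tied to one cholesteryl ester at ρ = 0.59, and a Proteobacteria taxon
tied negatively (ρ = −0.55) to six ether phosphatidylcholines. The lipid
catalogue enumerates 407 sum-composition names over 11 classes with
triglycerides (37%), phosphatidylcholines (25%) and
phosphatidylethanolamines (13%) dominating.

**Enzymatic panel.** TC/LDL/HDL/TG concentrations are Gaussian with typical
adult serum means and SDs (5.10 ± 1.02, 3.00 ± 1.21, 1.50 ± 0.33,
1.20 ± 0.71 mmol/L), loaded on the association latents so that the planted
taxon–lipidome links reappear against the matching analyte (TG positively
and HDL negatively on the TG-associated taxon's latent; TC/LDL on the
cholesteryl-ester taxon's latent). Concentrations are floored at
0.05 mmol/L; for TG (whose Gaussian marginal would go negative in ~5% of
draws) this floor plus the pooled repeated-measures sampling attenuates the
realised taxon–TG panel correlation from the nominal 0.60 to roughly 0.5.
We keep the floor (concentrations must be positive) and treat the planted
panel targets as nominal.

**Determinism.** All randomness derives from one integer seed through a
labelled splitting scheme (`seed × stream-label → child generator`), so a
fixed design reproduces byte-identical tables.

What the generator does *not* emulate: heterogeneous per-feature variance
components (every taxon shares the calibrated components, whereas real
genus-level data are strongly right-skewed — see the power discussion),
compositionality, detection floors/censoring, covariance between diet and
both omics, and phylogenetic correlation among taxa. Passing recovery tests
therefore demonstrates correctness of the statistical machinery under the
assumed model, not robustness to these real-data features.

## Stability statistics

Intra-individual stability is the Pearson correlation across features of one
subject's log10 profiles at two time points; inter-individual similarity is
the mean pairwise correlation between subjects' profiles at one time point,
computed within group. Missing values are handled pairwise-complete with a
minimum overlap of 10 features; subjects missing a time point are excluded
with a warning. Group differences in per-subject stability use the two-sided
Wilcoxon rank-sum test (all-tied input returns p = 1 with a warning).
Ordinary PCA (centred, no scaling) provides the sample-map visualisation; a
sparse variant would add a penalty parameter with no downstream consumer, so
plain PCA is used.

## Moderated intervention test

With one sample per subject per time point, sample-level and subject-level
random effects are confounded; the identifiable reading is subject blocking
via within-subject paired differences. The contrast is either the
within-group change (one-sample test on paired differences) or the
difference of changes between arms (two-sample). Per-taxon variances are
shrunk by empirical Bayes: a scaled-F prior is fitted to the observed `s²`
by matching moments of `log s²` (trigamma inversion by Newton iteration),
giving prior df `d0` and prior variance `s0²`; the posterior variance is
`(d0·s0² + d·s²)/(d0 + d)` and the moderated t has `d0 + d` df. If the
spread of `log s²` does not exceed pure chi-square scatter the moment system
is inconsistent and the implementation falls back to complete shrinkage
(`d0 = ∞`, pooled variance) with a warning. The implementation is verified
against the reference empirical-Bayes pipeline (limma's `lmFit`/`eBayes`
via Rscript) to ~1e-6 relative on a paired fixture. BH-adjusted p-values
and Storey q-values are both reported.

### Empirical power

For each replicate the observed samples × taxa matrix is permuted per taxon
(destroying real structure), two cells of n pseudo-subjects × 2 time points
are formed, a fold-change alteration (linear scale: ×2 ⇒ +log10 2; a flag
switches to log-scale insertion) is inserted into one random taxon in the
treatment cell, Gaussian noise with the data's average per-taxon SD is
added, and the full detection rule is applied (default: moderated contrast,
BH-adjusted p < 0.05 and |log2 effect| ≥ 1; the rule is injectable). The
detection rate is reported per sample size.

Under the calibrated generator the average per-taxon SD is √0.23 ≈ 0.48
log10 units, so a 2-fold insertion (0.30 log10) at n = 8 is essentially
undetectable (rate ≈ 0). Detection rates near 1 at n = 8 require an average
per-taxon SD an order of magnitude smaller — possible for real genus-level
data only because per-taxon variances are strongly right-skewed (profile
correlations constrain variance sums, while the *average* per-taxon SD can
be far smaller under skew). The generator deliberately keeps homogeneous,
calibration-faithful components rather than introducing a skew parameter
that nothing in the calibration determines; the power routine therefore
reports honest rates for the synthetic conditions, and high published rates
should be read as statements about particular low-noise data.

## Robust correlation screen

The biweight midcorrelation uses median centring, unscaled MAD and the
Tukey biweight `(1 − u²)² · 1[|u| < 1]` with `u = (x − med)/(9·mad)`
(tuning constant 9, the standard robust-correlation convention;
configurable). A zero MAD triggers a Pearson-style fallback for that vector
with a warning. The statistic factorises per vector, so the full
taxa × lipids matrix is one product of prepared column blocks. Two-sided
p-values use the Student-t approximation `t = r·√((n−2)/(1−r²))` with a
permutation alternative available; observations are pooled over the time
points the two tables share, without repeated-measures correction — this
mirrors the pooled design but is anti-conservative, since within-subject
dependence inflates the effective |r| tails relative to the nominal n.

Multiplicity over the whole grid uses Storey q-values: π0 is estimated on a
λ grid (0.05…0.95) with a cubic-spline smoother evaluated at the largest λ,
falling back to π0 = 1 when unstable; `q_i = min_{p_j ≥ p_i} π0·m·p_j /
rank(p_j)`, which reduces exactly to Benjamini–Hochberg at π0 = 1.
Significant pairs satisfy q < 0.05 and |r| ≥ 0.5 by default. For display
and biclustering, the r matrix is restricted to features with at least one
significant pair and ordered by two-way average-linkage (UPGMA) clustering
on correlation distance (1 − Pearson between rows/columns of the r matrix);
ties break by input order, and constant rows are placed deterministically.

## Plaid biclustering

The constant plaid model writes the matrix as `Y_ij ≈ μ0 + Σ_k μ_k ρ_ik
κ_jk` with binary memberships and a scalar effect per layer. Layers are
fitted greedily on residuals: initialisation seeds memberships from the
leading singular pair, examining all four sign orientations and a random
inclusion quantile in [0.5, 0.8]; updates alternate the layer effect (mean
of included cells) with release-style membership updates (keep a row/column
when its squared-error reduction is positive and ≥ (1 − release) of the
best one's; release = 0.7 both ways). A candidate layer is accepted only if
its sum of squares exceeds that of the best layer fitted to each of
`n_shuffles` entry-permuted copies of the residuals — a one-sided
permutation test at level 1/(S+1) per layer. The default S = 39 (level
2.5%) keeps the probability of any spurious layer on pure noise well below
5%; smaller S (e.g. the 3 shuffles some implementations default to) admits
a spurious layer on roughly a quarter of pure-noise inputs, which we judged
unacceptable for a detection method. Fitting stops at the first rejection
or at `max_layers` (default 5); everything is deterministic given the seed.

## Enrichment

Over-representation uses the exact hypergeometric 2×2 test with the
two-sided probability-mass rule (scipy's implementation, exhaustively
verified against direct enumeration for all tables with N ≤ 40); the
reported odds ratio is the sample estimate ad/bc. Lipid categories derive
from parsed names: carbon-count parity, saturation (SAFA/MUFA/PUFA = 0/1/≥2
double bonds), long chain (total carbons ≥ 54 by default — a tunable,
appropriate for triglyceride comparisons, since no community cut-off
exists), and ether linkage (trailing `e` on the double-bond count, e.g.
`PC(38:4e)`; the dialect is a regex override because platforms differ).
The default enrichment universe is "all lipids with ≥ 1 significant
correlation"; "all profiled lipids" is available, and the two can disagree
— both are supported precisely because the appropriate universe is a
judgement call. Taxon enrichment uses phylum / Clostridium-cluster labels
carried in the taxon annotation. Enrichment p-values are reported raw
(no correction across categories).

## Numerical and interface choices

- Lipid grammar: `CLASS(C:D[e])` with 11 classes; names with explicit
  slash-separated chains are outside the default grammar.
- All tables are TSV (samples as rows, first column the sample ID) with a
  canonical float format so write→read→write round-trips byte-identically;
  a `--transpose` flag accepts features-as-rows files.
- Degenerate inputs: constant vectors raise; zero-MAD vectors fall back to
  Pearson weighting; zero-margin contingency tables return p = 1; all-tied
  rank-sum input returns p = 1; constant matrices yield zero plaid layers
  and zero PCA variance.
- Problem sizes in the test suite (desk scale): 200-seed plaid recovery on
  60×100 matrices, 20-seed end-to-end screen recovery on the full
  131 × 407 cohort, 100-seed null calibration of the moderated test, and
  1000-replicate power runs.

## Known limitations

The screen's analytic p-values ignore within-subject dependence of pooled
observations (anti-conservative; the q threshold partially absorbs this).
The plaid acceptance test assumes entry exchangeability of residuals, which
correlation matrices violate mildly. Parameter recovery statements are
conditional on the generator's homogeneous variance-component model. The
number of accepted plaid layers is sensitive to the release and shuffle
parameters; it should be read as "distinct coherent blocks at this
stringency", not an estimate of a true cluster count.
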