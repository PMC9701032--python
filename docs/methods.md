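# Methods

## Measurements over methylation haplotype blocks

Every read contributes its haplotype — the ordered methylated('1') /
unmethylated('0') states of the consecutive CpGs it covers within one
region. From the pooled, count-weighted reads of one sample over one
region we compute seven measurements, all in [0, 1]:

- **AMF**: methylated CpG observations / all CpG observations.
- **MHL / MHL3**: every read is expanded into all of its substrings of
  consecutive CpGs; for each length *i* (1 ≤ *i* ≤ *L*, the region's CpG
  count), `P(MH_i)` is the fraction of observed length-*i* substrings that
  are fully methylated. The load is `Σ w_i P(MH_i) / Σ w_i` with `w_i = i`
  (MHL) or `i³` (MHL3). Lengths with no observed substring (ragged
  coverage) are dropped from both sums, which keeps the load defined for
  partially covering reads; with *L* = 1 the load reduces exactly to AMF.
- **UMHL / UMHL3**: identical with fully unmethylated substrings. By
  construction the unmethylated loads of a read set equal the methylated
  loads of the bit-flipped read set, a symmetry the tests assert bitwise.
- **MHFm / MHFu**: among reads covering *every* CpG of the region, the
  fraction that are all-'1' / all-'0'. Restricting to full-span reads is a
  deliberate convention: partial reads cannot witness a full-region
  haplotype. An any-span variant would change the denominator
  per-locus; we keep the full-span reading because it makes
  MHFm + MHFu ≤ 1 with equality exactly when every full-span read is pure.

Missingness policy: a computable 0 is a value. A cell is missing only when
(a) the region's total read depth in that sample is `< min_depth`
(default 10, strict), or (b) a measurement's denominator is empty (no
reads; no full-span read for MHFm/MHFu).

## Marker discovery

Tissue-style contrasts (tumour vs para-tumour, tumour vs healthy plasma)
first drop regions missing in more than 10% of samples or with sample
variance below 0.02 (both strict), then test each region with a two-sided
Wilcoxon rank-sum (exact enumeration when both groups have < 10 tie-free
values, tie-corrected normal approximation otherwise) and keep regions
with Benjamini–Hochberg q < 0.05.

The variance screen belongs to the *undiluted* contrasts: in plasma the
case shift is scaled down by the tumour fraction (expected AMF shift
f·Δ ≈ 0.08 under the default design), so a 0.02 variance floor would
remove essentially every region, true markers included. The plasma
pipeline therefore applies only the NA-rate filter by default
(`apply_variance_filter` restores the screen).

Plasma-vs-plasma selection is a resampling scheme: in each of 500
iterations, 20 controls are drawn to balance the cases; both groups are
split 15+15 discovery / 5+5 validation; differential regions (q < 0.05) in
the discovery split train a random forest (500 trees, √p features per
split) whose validation AUC must reach 0.75 for the iteration to count;
regions credited in more than 300 iterations are selected. All
randomness derives from one seed; iterations with no differential region
count as failures and are logged.

A literature set takes regions overlapping the strand-aware promoter
window [TSS − 1500 bp, TSS + 1000 bp] of listed genes. The final panel is
(T2T ∩ T2P) ∪ (T2T ∩ literature) ∪ P2P, deduplicated with provenance.

## Classifier construction

- **Measurement selection**: per marker, one logistic regression of the
  label on each measurement; smallest two-sided Wald p wins, ties broken
  by the fixed order amf, mhl, mhl3, umhl, umhl3, mhfm, mhfu. Under
  perfect separation the maximum-likelihood Wald p is meaningless
  (standard errors diverge), so the fit falls back to a Firth
  (Jeffreys-prior) penalised logistic regression, which is
  scale-equivariant and keeps a separating measurement's p small; the
  record is flagged. A windowed chi-square screen (10 equal bins over
  [0, 1], closed right edge at 1.0, df = non-empty bins − 1, no continuity
  correction) is provided as the alternative selection route.
- **Preprocessing**: markers detected in ≥ 90% of training samples are
  kept. Each marker is scaled by its training median and 25–75%
  interquartile range (zero-IQR markers dropped with a warning); residual
  missing values are imputed from the 5 nearest *training* samples, with
  nan-Euclidean distances over mutually observed markers in the scaled
  space (scikit-learn's KNNImputer; neighbour ties resolved by its
  internal ordering). Validation/test samples reuse the training scaling
  parameters and training donors.
- **Incremental selection**: markers enter ranked by selection p. The set
  starts with the top marker; each next marker is accepted iff the mean
  10-fold stratified CV AUC of a linear SVM (C = 1) on the enlarged set
  does not fall below the current set's (ties accept). The fold assignment
  is fixed once per seed and reused for every candidate, so acceptance
  decisions are comparable and the whole trace is reproducible and
  auditable.
- **Final model**: the SVM is refit on all training samples; its signed
  margin is mapped through a logistic link fitted on the training margins,
  giving a probability-like score; the decision cutoff is Youden's J on
  the training ROC (a fixed-specificity mode, default 0.89, is available
  for sensitivity comparisons). The model serialises to versioned JSON —
  support vectors, link, cutoff, preprocessing parameters and donor pool —
  and a reloaded model reproduces scores to 1e-9.
- **CA19-9 integration**: logistic regression on (score,
  log10(CA19-9 + 1)); the log transform tames the heavy right skew of
  U/ml values. Samples without CA19-9 are excluded from this model only.

## Evaluation statistics

AUC uses the Mann–Whitney identity with half credit for ties (invariant
under monotone score transforms). Bootstrap AUC CIs resample within class
(prevalence preserved), 1000 replicates by default, percentile bounds; the
replicate variance feeds the chi-square statistic
`T = (AUC_a − AUC_b)² / (s²_a + s²_b)`, referred to χ²(1). T ignores the
covariance of the two AUCs, so it is calibrated when the two scores'
shared component is weak and conservative when they are strongly
correlated; the calibration test exercises the noise-dominated regime, and
the DeLong test (placement values, full covariance) is provided for
correlated comparisons. Sensitivity/specificity intervals are exact
Clopper–Pearson (beta quantiles; bounds exactly 0/1 in the degenerate
corners). McNemar comparisons use the exact two-sided binomial on
discordant pairs. Enrichment is the upper-tail hypergeometric.

## Synthetic cohort

The generator emulates the features the pipeline's statistics rely on:

| parameter | default | meaning |
|---|---|---|
| n_regions / n_true_markers | 200 / 20 | panel size and planted signal |
| splits | train 60/60, validation 30/30 | cases/controls per cohort |
| mu_low / mu_high / p_high | 0.15 / 0.85 / 0.5 | bimodal background modes |
| kappa | 15 | Beta concentration; between-sample AMF sd ≈ 0.09 |
| delta | 0.4 | tumour methylation shift, direction away from the mode |
| tumour_fraction | 0.2 | fraction of case reads from the tumour level |
| rho | 0.7 | within-read co-methylation probability |
| coverage | NB(mean 50, dispersion 10) | reads per region per sample |
| span_p | 0.85 | read span = 1 + Binomial(L−1, span_p) CpGs |
| cpg_count_range | [3, 8] | CpGs per region |
| missing_region_rate | 0.02 | whole-region dropouts |
| CA19-9 | lognormal, medians 4 / 421.6 / 109.6 | healthy / PDAC / CP U/ml |
| lewis_negative_fraction | 0.1 | cases forced below 37 U/ml |

The tumour shift is applied at *read* level — a fraction f of a case's
reads is drawn from the shifted level — mirroring ctDNA dilution rather
than shifting the bulk mean; consequently the expected case-control AMF
difference at a true marker is f·Δ, which the tests check against the
analytic value. The co-methylation switch ρ makes reads block-correlated,
so haplotype loads (MHL, MHFm) genuinely differ from AMF and measurement
selection has something to choose between.

What the generator does **not** emulate: real genome coordinates and CpG
density structure, bisulfite conversion errors, fragment-length biases,
batch effects, age/sex covariate structure in methylation, or correlations
between regions. Passing recovery tests therefore demonstrates that the
pipeline's statistics behave as designed under their own assumptions — not
that the cohort-dependent headline accuracies of any real study would be
reproduced.

## Numerical and design choices

- 0-based half-open coordinates throughout; CpG positions are the
  forward-strand C; reads crossing a region boundary are truncated at load
  time.
- MHB partitioning pools reads over samples, computes LD-style r² from the
  2×2 co-methylation counts of each adjacent CpG pair, and emits maximal
  runs of ≥ 3 CpGs with r² ≥ 0.5; pairs with no co-covering reads or a
  constant margin are block boundaries. This follows the community
  convention; the exact construction used upstream of published panels is
  not restated anywhere authoritative, so blocks are convention-faithful
  rather than a reproduction.
- "Selected more than 300 times" is strict (> 300), and the incremental
  rule accepts ties; both are configurable.
- The discovery-phase tests run on one configured measurement (AMF by
  default); per-marker measurement selection happens at classifier
  construction, where it can be validated by cross-validation rather than
  multiplying the discovery-phase test burden.
- When no region clears the FDR threshold the pipeline falls back to the
  10 smallest-p regions (logged) so a model always exists and a null
  cohort is evaluated honestly rather than erroring out.
- Problem sizes in the test suite (cohorts of tens of samples, hundreds of
  regions, 500 resampling iterations, 500–2000 simulation replicates) were
  chosen as the smallest sizes at which the checked quantities are stable;
  the pipeline itself has no scale assumptions beyond memory.

## Known limitations

- The haplotype file dialect carries a strand column but metrics ignore
  it; reverse-strand collapsing is assumed done upstream.
- Firth p-values under separation are approximate (Wald on the penalised
  fit); profile-likelihood intervals would be tighter.
- The T statistic's independence assumption makes it conservative for
  strongly correlated models — use the DeLong test there.
- KNN imputation quality degrades when a sample shares few observed
  markers with the training pool; with no shared markers the imputer falls
  back to column means.
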