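# Methods

This note documents the models, procedures, parameter choices and known
limitations of `mapkstress`. It covers the science the package encodes
and the design decisions taken where more than one reasonable choice
existed.

## Study design and containers

The experimental design is 18 bulk RNA-seq libraries from *Beauveria
bassiana*: the wild type under no stress plus four stress agents
(1 M sorbitol — osmotic; 16 µM menadione — oxidative; 25 µg/mL Congo
red — cell wall; 32 °C — heat) at 0.5 h ("acute") and 12 h
("sustained"), and each MAPK deletion mutant (ΔHog1, ΔSlt2, ΔMpk1)
under no stress plus its sensitive stress at both times. Each library
pools three biological replicates mixed before sequencing, so the
design has one column per condition and no within-condition replication.
Samples are named `Strain_Stress_Time` with short stress codes
(CK/SOB/MND/CR/HT). `CountMatrix` carries the integer counts and
per-gene transcript lengths; `SampleDesign` parses the names into
(strain, stress, time) and derives the binary trait indicators used for
module–trait correlation.

## Normalization

* **Zero filter.** A gene is kept when its count is zero in at most
  `max_zero_samples` libraries (default 12 of 18, i.e. detected in at
  least six). The filter is idempotent and order-preserving.
* **FPKM.** count × 10⁹ / (length_bp × library size), with library size
  the post-filter column sum. The +1 pseudocount is applied at the log
  step, not inside FPKM, so FPKM itself stays a pure rate.
* **log2 + quantile.** log2(FPKM + 1), then each column's order
  statistics are replaced by the across-column mean of order statistics.
  Tie policy: the default assigns tied values distinct reference
  quantiles by stable sort position, which preserves the defining
  invariant of quantile normalization — every column shares an identical
  sorted multiset afterwards. Averaging the reference quantiles across a
  tied group (limma's convention) is available as `tie_policy="mean"`;
  it treats tied inputs symmetrically but breaks exact multiset equality
  whenever columns differ in their tie patterns (zero counts make this
  ubiquitous), so it is not the default.
* **logCLR.** Per gene across samples: p_j = (count_j + 1)/Σ(count_j + 1),
  then ln p centered to row mean zero. Natural log is used for the CLR
  (the compositional-data convention); fold changes elsewhere use log2.
* **TMM.** Trimmed mean of M-values between each sample and a reference
  column (the one whose 75th percentile of depth-scaled counts is
  closest to the mean of those percentiles). M values are trimmed 30%
  on each side, A values 5%, and the surviving M values are averaged
  with inverse asymptotic-variance weights; factors are normalized to
  geometric mean 1. The co-expression compendium transform applies TMM
  scaling to the counts first and logCLR second — TMM is defined on
  counts, not on CLR values — and records that order in the matrix
  metadata.

## The mutant-responsiveness DEG classifier

Fold change is log2((FPKM_st + 1)/(FPKM_nor + 1)) against the same
strain's unstressed time-0 baseline. Screening labels: DEG at
|log2FC| ≥ 2, silent at |log2FC| ≤ 0.5, both boundaries inclusive.
The mutant-responsiveness rule compares WT and mutant under the same
stress × time:

* `up_in_mutant`: log2FC_WT ≤ −2 and log2FC_mut ≥ −0.5;
* `down_in_mutant`: log2FC_WT ≥ 2 and log2FC_mut ≤ 0.5.

Note the direction semantics: "up in the mutant" means the WT
down-responds while the mutant does not — a relative up-regulation of
the mutant against its own baseline-normalized WT comparison, not an
absolute induction. The silent criterion bounds the mutant fold change
on one side only, exactly as the screening inequalities are written;
whether the intent was a symmetric |log2FC_mut| ≤ 0.5 band cannot be
settled, so a `two_sided` mode is provided and the mode in force is
recorded with every DEG set. With no replication in the pooled design
there is no variance estimate, hence no statistical test — the
classifier is a thresholded effect-size rule by construction.

Set algebra: time-point overlap counts co-up, co-down, total
(labelled in both) and discordant (labelled in both, opposite
direction); crosstalk intersects the up (resp. down) label sets of all
three mutants. `published.py` keeps the study's reported per-contrast
up/down counts as input data and rebuilds explicit label sets with those
cardinalities so all derived totals, percentages, overlap breakdowns and
crosstalk counts are recomputed by the same set-algebra code the
pipeline uses. One reported breakdown (the oxidative mutant's 97-gene
overlap with 88 co-up) is only consistent with the acute contrast's
major side carrying the up labels, and is reconstructed in that
orientation.

## Co-expression

* **Gene selection.** The union of genes labelled in at least one mutant
  contrast, in deterministic sorted order.
* **k-means compendium.** Squared-Euclidean k-means on logCLR gene
  profiles, k-means++ seeding, 10 restarts, best inertia kept;
  deterministic given a seed.
* **Soft threshold.** For each power on the grid 1..20, adjacency
  a = |r|^β (unsigned default; signed ((1+r)/2)^β available), gene
  connectivity k = row sums, and the scale-free fit R² from the linear
  regression of log10 p(k) on log10 k over 10 equal-width connectivity
  bins (fit forced to 0 when the slope is not negative). The smallest
  power reaching R² ≥ 0.8 is chosen; if none qualifies the power with
  maximal fit is returned with a warning. Unsigned adjacency is the
  default because the module–trait map needs both strong positive and
  negative correlations, which unsigned detection plus signed trait
  correlation reproduces.
* **TOM and modules.** TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) +
  1 − a_ij) with unit diagonal. Module detection is average-linkage
  clustering of 1 − TOM with a *static* cut at height 0.99, clusters
  below `min_module_size = 30` set to grey, then iterative merging of
  the most correlated module pair while any eigengene correlation
  exceeds 0.75. This static-cut-plus-merge procedure is deliberately
  simpler than the dynamic-hybrid tree cut: it is fully specified,
  deterministic and testable; module counts on real data will differ
  from a dynamic-cut run. Labels are colors in decreasing module size
  (turquoise, blue, brown, ...), grey meaning unassigned.
* **Eigengenes.** First principal component (SVD) of the
  row-standardized module submatrix, unit norm. Sign is fixed
  self-referentially — the largest-magnitude entry is made positive —
  so the eigengene is invariant to gene order and to flipping the sign
  of every module gene; orienting against the module mean profile
  instead would flip with the genes. Variance explained is reported.
* **Module–trait.** Pearson correlation of each eigengene with each
  binary trait indicator; two-sided p from t = r√(n−2)/√(1−r²) with
  df = n − 2. Constant traits yield missing values, not zeros. At
  n = 18 this reproduces the reported module–trait pairs within
  rounding of r (e.g. r = 0.78 → p = 1.35 × 10⁻⁴).

## Enrichment

One-sided hypergeometric upper tail (equivalently Fisher exact,
"greater"): p = P(X ≥ k) for a query of n genes overlapping a K-gene
term in a universe of N. The universe defaults to all genes that
survive the zero-count filter — the analyzed gene space — not the whole
genome. Benjamini–Hochberg q-values are computed across all tested
terms of one map; both raw p and q are reported because published
thresholds may refer to either.

## Phenotype assays

* **RGI.** (Dc − Ds)/(Ds − d) × 100 with d = 5 mm, implemented exactly
  as stated. The more common convention (Dc − Ds)/(Dc − d) × 100 is
  available behind `formula="conventional"` and always labelled in
  output; the published RGI values cannot adjudicate between the two
  because the raw diameters are unpublished. RGI is strictly decreasing
  in Ds and errors when Ds ≤ d.
* **ECAR.** Ordinary least-squares slope of signal vs time per well
  within a window (default 30–100 min, after the 30-min dark
  equilibration), group slope = mean over wells of a type minus the
  mean blank slope. Hexokinase-mediated ECAR = measurement − 2-DG
  control; 2-deoxy-D-glucose competitively inhibits hexokinases, so the
  difference is the hexokinase-dependent component. Units stay relative
  fluorescence per minute; no RFU→mpH calibration is attempted (kit
  constants unpublished).

## The synthetic-data generator

`simulate_counts` draws the 18-condition design with, per gene g and
library s, mean μ_gs = libsize_s · w_g/W · 2^(planted effect) ·
2^(loading_g · z_bs), where w_g is a lognormal relative abundance
(log2-normal with mean 5, sd 1.8) and libraries are 4–6 million counts.
Counts pool three gamma-perturbed biological replicates (per-replicate
dispersion φ, variance μ + φμ²) and add Poisson sequencing noise,
mirroring the pooled-library protocol; the pooled library behaves
negative-binomially with effective dispersion φ/3. `noise_model="none"`
returns rounded means for exact-recovery checks. Defaults: 2000 genes,
dispersion 0.05, 200 planted WT-responsive/mutant-silent genes
(25 per stress × time, alternating signs at |log2 effect| 3, mutant
effect exactly 0), and three 60-gene co-expression blocks with loadings
around 0.8.

Block latent factors are drawn per sample and orthogonalized (QR,
including the intercept) so between-block Pearson correlation is
exactly zero — the well-separated-blocks setting the recovery tests
assume; at 18 samples unorthogonalized factors can correlate by chance
strongly enough to merge planted modules. `loading_spread` controls the
relative spread of per-gene loadings: the default 0.25 gives tight
blocks (within-block |r| ≈ 0.9); a larger spread (0.6) with graded
block loadings produces the hub/periphery connectivity continuum under
which soft-threshold selection attains the scale-free fit target.

Growth and plate-reader simulators carry their configured truth
explicitly: colony diameters are Gaussian around true control/stressed
diameters (the default truth table encodes the reported RGI landscape,
e.g. 99.04% for the osmosensing mutant on sorbitol/SDA against 58.69%
for the WT), and ECAR wells are linear trends plus noise with slopes
set so the WT's hexokinase-mediated ECAR exceeds the mutant's by 58%
and the mutant's total ECAR is 34% lower.

What the generator does *not* emulate: GC/length biases (counts are
length-independent by design, so FPKM math is testable in isolation),
batch effects, outlier libraries, overlapping module membership, and
any coupling between the phenotype and transcriptome layers. Passing
recovery tests therefore demonstrates correctness of the algorithms
under the stated noise model, not robustness to artifacts real
libraries may carry.

## Numerical choices and degenerate inputs

Fold changes require finite FPKM (guaranteed by the pseudocount);
zero-variance genes are an error in adjacency/TOM (listed by id) and in
eigengene computation; constant traits and zero-variance samples
propagate as missing values rather than zeros; single-column quantile
normalization degrades to the log transform with a warning; an
all-genes-removed filter result warns rather than errors. All
stochastic steps (simulators, k-means) are seeded; identical
configurations reproduce byte-identical outputs.

## Problem sizes

The test and acceptance runs use the generator's default scale — 2000
genes × 18 libraries, 180 block genes for module recovery, a 1000-gene
graded fixture for soft-threshold selection — sizes at which every
pipeline stage, including TOM construction and tree cutting, is exact
(no block-wise approximations). The implementation holds dense
gene × gene matrices, so it targets the study's scale (thousands of
selected genes), not >20k-gene networks.

## Known limitations

* No statistical testing of differential expression is possible in the
  pooled design; the classifier is a fold-change rule and inherits its
  sensitivity to the 0.5 silent boundary (planted-truth recall is
  ≈0.92–0.97 at dispersion 0.05, the misses being borderline silent
  calls).
* The static tree cut will not reproduce a dynamic-hybrid module
  decomposition gene-for-gene; module counts published for the real
  data (80 k-means, 12 network modules over 4646 genes) depend on
  settings that are not recoverable and are not targets here.
* FPKM-based fold changes are compositionally biased when libraries
  shift strongly; TMM is provided for the compendium route but the
  classifier follows the FPKM formula as specified.
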