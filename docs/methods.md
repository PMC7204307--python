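# Methods

This note documents the models, conventions, and numerical choices behind
`cinscore`, and what the synthetic-data tests do and do not establish.

## Copy-number event model

Input segments carry a GISTIC-style log2-like value. Conventions:

* **Thresholds.** Gain iff value > 0.3, loss iff value < −0.3; both strict,
  so a value of exactly ±0.3 is neutral. Thresholds are parameters of
  `threshold_segments`.
* **Coordinates.** 0-based half-open everywhere. SEG input is assumed
  0-based half-open; the CLI flag `--coords 1incl` declares 1-based
  inclusive input, converted on read.
* **Arm splitting.** A segment spanning the centromere is split at the p/q
  boundary with the value copied to both parts; total altered base pairs
  are conserved exactly (tested against an elementary-interval oracle).
* **Broad vs focal.** The 98% rule is applied to the *merged* altered
  length per (sample, arm, direction), not to single contiguous segments,
  because segmentation fragments arbitrarily. The test is strict
  (fraction > 0.98; exactly 98% is focal). At most one broad event is
  emitted per (sample, arm, direction); gains and losses on the same arm
  count separately, and a whole-chromosome event counts as two arm-level
  broad events. Below the broad threshold, one focal event is emitted per
  maximal altered run — a deterministic, oracle-checkable rule.
* **Scores.** Broad-CNA score = broad events / total arms (so a fully
  aneuploid genome altered in both directions on every arm scores 2);
  focal-CNA score = focal events / total genes in the catalog. TMB divides
  the nonsynonymous mutation count by the exome size in Mb, default
  299.029409. Fusion score = events / total fusion types. MSI is a
  passthrough column on the MANTIS scale; no MSI computation is performed.

## Signature activation

The single-sample Z-score method: each present signature gene is
standardized to zero mean and unit variance across the scoring cohort, and
a sample's score is the direction-signed sum of its member z-values divided
by √k (Stouffer form; a plain mean-of-z variant is available via
`combine="mean"`). Consequences used by the tests: the score of a random
gene set on structureless data is asymptotically standard normal, the score
is invariant to affine rescaling of any member gene, and the cohort mean is
0 when scored on the standardization cohort itself. Standardization is
per cohort; scores are therefore relative to the scoring cohort, not
transferable across cohorts without restandardization.

Zero-variance members are excluded with a warning (their z is undefined);
missing members are skipped and logged. CIN-high/low stratification
defaults to the cohort median split (strictly above the median is high);
tertile mode (lowest/middle/highest) is provided for descriptive use.

The shipped CIN70 list is sourced from the original 70-gene
chromosomal-instability signature publication (Carter et al. 2006), with
legacy aliases mapped to modern HGNC symbols (TOPK→PBK, CDC2→CDK1,
STK6→AURKA, CDC45L→CDC45, BRRN1→NCAPH, CNAP1→NCAPD2, ch-TOG→CKAP5, …).
A few legacy probe identifiers have no unambiguous modern symbol; the list
should be treated as a faithful working reconstruction rather than a
byte-exact copy of the original table. PC-CIN's seven members are exact.

## Count preprocessing

Genes are kept when their raw counts *summed over all libraries* reach 2
(the stricter in-every-library reading is available via `per_library=True`).
TMM follows the original trimmed-mean-of-M-values algorithm: reference
library = the one whose 75th-percentile count fraction is closest to the
cohort mean; M and A computed on genes positive in both libraries; double
trimming at 30% (M) and 5% (A); precision weights from the delta-method
binomial variance; factors rescaled to geometric mean 1. Normalized
expression is log2 CPM over effective library sizes with pseudocount 0.5.
The implementation reproduces edgeR's `calcNormFactors(method="TMM")` to
~1e-10 on a frozen fixture, and recovers a known pure scaling factor
between libraries to well under 1%.

## Differential expression

Per gene, two statistics of the A-vs-B contrast: a Welch t (mean
difference over unpooled SEs) and a log2 median-ratio (difference of group
medians on the log2 scale; robust to outlier libraries). Both are referred
to an empirical null built from random label permutations *pooled across
genes* (stable tails at moderate permutation counts; with n_perm
permutations and G genes the smallest attainable p is 1/(n_perm·G+1)).
Two-sided p-values compare magnitudes and carry a +1 correction.

The two p-values are combined as a signed Stouffer z. Because the two
statistics are positively correlated, a normal reference for the combined z
would be anti-conservative; the combined z is therefore referred to its own
permutation null (the same combination applied to every permuted statistic
pair). This keeps the false-discovery proportion of DEG calls at or below
the nominal BH level on null cohorts, which the acceptance suite verifies
by simulation (200 null cohorts, 500 genes, 10 vs 10).

Design points: the null depends only on the *unordered* sample partition
(pooled columns in sorted sample order, smaller group size drawn first), so
swapping the contrast's groups negates fold changes and preserves p-values
exactly. BH is used for FDR. The fold-change threshold 1.5 is linear:
|log2 FC| ≥ log2 1.5. DEG = (q < 0.05) ∧ (FC ≥ 1.5).

Power at the calibrated thresholds: a 2-fold planted shift is recovered
with recall ≥ 0.9 when it stands several standard errors above the count
noise (the power simulations use dispersion 0.1 at n = 20 per group, a
≈7 SE shift). At the cohort-default dispersion 0.3 the same shift is only
≈3.4 SE and recall drops to roughly one half — the honest cost of a
calibrated test at that noise level, visible in the README example where
the bimodal M1 mixture further dilutes the contrast.

Cross-cohort "shared" DEGs are the focal cohort's DEGs found in at least
one external cohort's set; all Venn regions are reported alongside.
Directional concordance calls a shared gene concordant when its
fold-change sign agrees in every cohort where it is a DEG; with no shared
genes the fraction is reported as missing, not 0.

## Gene set enrichment

Ranking by Signal2Noise: (μ_A − μ_B)/(σ_A + σ_B) with each σ floored at
0.2·|μ| (0.2 when μ = 0), the canonical definition; ties break by gene id,
and the tie rule is documented because the enrichment score depends on
order. The enrichment score walks the ranked list with hit increment 1/k
and miss decrement 1/(N−k) — the classical equal-weight KS running sum —
and ES is the signed maximum deviation. The |metric|-weighted variant
(GSEA-default style) is available via `weight=1`; equal weight is the
package default as the plain KS statistic. Significance uses random gene
sets of the matched size (not phenotype permutation), with
p = (1 + #{|ES₀| ≥ |ES|})/(n_perm + 1). The leading edge is the members at
or before the running-sum maximum (positive ES) or at or after the minimum
(negative ES), in rank order.

Distillation intersects the top k leading-edge genes with an externally
curated annotation mask (e.g. mitosis regulators), preserving rank order.
Curated biology is an *input*: the package never computes functional
annotation. The shipped top-19 leading-edge context and mitosis mask are
synthetic stand-ins (marked as such in `signatures.py`): the seven
mitotic-regulator genes and their identity are exact, the twelve
interleaved context genes are a plausible reconstruction, sufficient to
exercise the distillation contract.

## Stage classifier

Expression is restricted to the signature genes, standardized per gene
(correlation-mode PCA, since genes sit on different scales), projected onto
the top two principal components, and classified with an RBF SVM (C = 1,
kernel width by the median heuristic on training 2-D distances).
Evaluation defaults to stratified 5-fold cross-validation with all
preprocessing — standardization, PCA, kernel width — learned inside each
training fold; resubstitution is available and labelled as such. AUC uses
a threshold sweep with half-credit ties, identical to the Mann–Whitney
pair-counting statistic (asserted against an all-pairs oracle and against
scikit-learn independently).

## Synthetic cohort generator

Each sample draws a latent CIN level c from its stage class's normal
distribution (SD 0.15, truncated at 0); for M1 classes a two-component
mixture puts weight `m1_bimodal_weight` (default 1/3) on a low-CIN mode
(mean 0.2), reproducing the observed bimodality of de novo metastatic
cases. Defaults emulate a 99-case biopsy cohort: 23 M0-NM, 6+7 M0-oligo/
poly, 25+38 M1-oligo/poly, with latent means rising from 0.2 (M0-NM) to
1.0 (M1-poly). The M0-oligo/M0-poly means (0.45/0.6) are interpolations;
no quantitative description of those groups' expression differences was
available to calibrate against.

The latent level drives all readouts jointly:

* each arm acquires a broad event with probability clip(0.35·c, 0, 1);
  broad segments cover 99% of the arm (safely above the 98% rule) with
  |value| in [0.35, 1]; focal events (Poisson, mean 4) occupy disjoint
  tenth-of-arm blocks on arms without a broad event, alongside neutral
  filler segments with |value| < 0.3 — so per-chromosome non-overlap holds
  by construction and class membership is unambiguous;
* counts are negative binomial with var = μ + φμ² (φ = `dispersion`,
  default 0.3, a typical bulk-RNA-seq value); baseline log2 means are
  uniform on [3, 9]; planted signature genes shift by `cin_effect`·c log2
  units (default 1);
* nonsynonymous mutations ~ Poisson(200 + 300c) (≈0.7–1.7/Mb, the scale of
  primary prostate tumors), fusions ~ Poisson(1 + 3c) over 6 fusion types,
  MSI ~ Beta(1.2, 8), and outcome flags (BCR/CRPC/death) follow a logistic
  function of c.

One seed sequence drives a cohort; per-sample child streams are spawned
deterministically, so identical configs give byte-identical cohorts.
`signature_gene_symbols` optionally names the planted genes with real
symbols (e.g. the CIN70 list) so shipped signatures score directly.

What the generator does *not* emulate: tumor purity and ploidy, allele-
specific copy number, gene-length and GC biases, batch effects, correlated
gene modules beyond the planted signature, and any read-level artifacts.
Passing tests therefore establish the correctness and calibration of the
algorithms under the stated statistical model, not performance on real
sequencing data.

## Problem sizes and numerical choices

The test and acceptance workloads are scaled for quick, deterministic
runs: 1000 random segment tables (≤ ~10² segments each) for the exact CNA
oracle; 200 null cohorts (500 genes, 10 vs 10, 300 permutations) for FDR
control; 20 seeds for power, joint-driver, and GSEA checks; 200 random
instances (N ≤ 50) for the exhaustive ES oracle. Empirical p-values use
+1 corrections throughout; permutation counts below 100 trigger warnings.
Degenerate inputs fail loudly: constant score vectors cannot be
stratified or correlated (reported as undefined, never 0), empty gene
catalogs and zero-total libraries are configuration errors, and a gene set
covering the whole ranked list has no defined ES.
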