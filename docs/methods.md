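# Methods

## The noise statistic

For a gene-by-cell count matrix with counts c_ij over m cells, cells with
fewer than 100,000 total counts are removed, then genes detected in fewer
than 1% of cells. Per-cell size factors s_j come from a simplified
pooled-deconvolution scheme: cells are placed on a ring ordered by library
size; for each pool size in {20, 40, 60, 80, 100} (capped at the cell
count), every ring window is summed and compared against the average
pseudo-cell, the per-gene ratios robustified by a median; each pool
contributes one linear equation in the per-cell factors, and the system —
plus a low-weight per-cell library-size anchor that keeps it full rank —
is solved by sparse least squares. Non-positive estimates fall back
per-cell to library-size factors with a warning; below 20 cells the
library method is used outright. Factors are rescaled to geometric mean 1.

Writing n_ij = c_ij / s_j and m_i for the per-gene mean normalized count
(reported on the log2 scale as mu_i = log2 m_i), the default noise
statistic follows the Brennecke parametrization:

    CV2_i  = Var(n_ij) / m_i^2
    E[CV2] = a0 + a1 / m_i          (gamma GLM, identity link, IRLS)
    rCV2_i = | CV2_i - E[CV2_i] |

For negative-binomial counts with dispersion phi, CV2 = 1/m + phi, so a1
is expected near 1 and a0 near the typical dispersion, and the residual
isolates a gene's dispersion excess from its expression level. An
alternative reading — variance of log2(n + 1) over mu^2, fitted against
1/mu — is available as `cv2_on="log2"`; we verified on negative-binomial
simulations that it leaves a strong residual mean dependence (Spearman
rho between rCV2 and mu of −0.3 to −0.5), defeating the purpose of the
residualization, and therefore made the linear-scale parametrization the
default.

**Robustness iteration.** The gamma GLM is fit twice: after the first
pass, genes whose relative residual (CV2 − fit)/fit lies more than 3
robust standard deviations (1.4826 × MAD) from the median are excluded
and the curve refit. A handful of strongly hyper-variable genes otherwise
carries enough leverage to tilt the reciprocal coefficient by ±0.4 across
realizations, and any error in a1 induces a spurious 1/m gradient in the
residuals. Under clean gamma noise the rejection removes ≲0.5% of points
and the bias is negligible (verified: recovery of a planted unit curve
stays within 3 standard errors). Disable with `outlier_sd=None`.

**Fit inclusion.** Genes with mu ≤ 0.1 (log2 scale) keep their CV2 but
are excluded from the fit and get no rCV2: the reciprocal covariate is
unbounded there. Exact zeros in CV2 (constant genes) are likewise
excluded from the gamma fit, which requires positive responses.

### A structural property of the absolute residual

rCV2 folds the signed residual about the fitted curve. Genes *below* the
curve therefore gain rCV2 as their dispersion *decreases*. Two
consequences, established on simulations and respected throughout the
package:

1. A feature that multiplicatively scales dispersion for all genes is
   **not** reliably detectable with the expected sign by a robust
   (median-type) regression on rCV2 — the bulk of genes sits below the
   mean-fitted curve, where the association reverses. Ordinary least
   squares, driven by the upper tail, keeps the right sign; Huber
   regression does not.
2. Features whose effect is concentrated in the *noisy tail* — changing
   which genes are hyper-variable — shift the location of the rCV2
   distribution monotonically and are detected well.

The synthetic generator plants effects of the second kind (see below);
analyses of real data with this pipeline inherit the same caveat.

## Robust feature screens

Each genomic feature is regressed on rCV2 with Huber M-estimation
(tuning constant 1.345, ≈95% efficiency at the normal; scale by MAD;
IRLS, tolerance 1e−8, max 200 iterations; Tukey bisquare behind a flag).
rCV2 is long-tailed, so a mean-based fit would let a handful of extreme
genes dictate coefficients. The intercept is always included; per-feature
coefficients are tested two-sided with t on n − p degrees of freedom
using the M-estimator covariance. Rank-deficient designs are rejected
with the collinear columns named. No multiple-testing correction is
applied across features (each is reported at p < 0.05 as in the screens
this mirrors); rows with missing features are dropped listwise per model.

Features are z-scored (over genes with defined values) so coefficients
are comparable across features; zero-variance columns are flagged and
left unstandardized.

The promoter-category analysis regresses rCV2 on indicator columns for
{active, bivalent, low} with *repressed* as the reference, plus
standardized island size, reusing the same robust fit.

## Annotations

Promoters span −1 kb to +500 bp around the TSS: on the + strand
[tss−1000, tss+500), mirrored to [tss−500, tss+1000) on the − strand;
intervals reaching past position 0 are clipped and flagged. All
coordinates are 0-based half-open (BED-native); GTF records are converted
on read. The TSS of a gene record is its 5′-most base (start on +, end−1
on −). Transcript-structure features (total exonic length, exon count,
mean exon length) use the longest annotated transcript, ties broken by
transcript id. CpG islands are assigned by ≥1 bp overlap with the
promoter; among several overlapping islands the one with maximal overlap
wins, ties going to the longer island. GC content is the G+C fraction
over unambiguous bases only (N excluded from numerator and denominator).

## Chromatin classification

ChIP and matched input window counts (non-overlapping 200-nt grid) are
depth-normalized to counts per million; enrichment is
log2((chip+1)/(input+1)). Promoter signal is the unweighted mean over
windows overlapping the promoter, per replicate, then averaged across
replicates. The H3K4me3 threshold is the lowest interior local minimum of
a Gaussian KDE (Silverman bandwidth, 512-point grid over the data range)
lying between the two largest modes; a unimodal density raises an error
that points to the manual override. The H3K27me3 signal is long-tailed
without a usable minimum, so its threshold is the mean over promoters. A
mark counts as present when the signal strictly exceeds 1.5× its
threshold; both present ⇒ bivalent, only H3K4me3 ⇒ active, only
H3K27me3 ⇒ repressed, neither ⇒ low (kept explicit rather than merged).
When a threshold is ≤ 0 the 1.5× multiplier lowers rather than raises
the bar; a warning is emitted.

## Early-response enrichment

Genes (or CAGE peaks, with islands assigned within a 500-bp window
centred on the peak) are restricted to those with an island, then ranked
by descending log2 fold change separately in the early and the late
consecutive-time-point comparison. The r-th early gene is paired with the
r-th late gene for r = 1..250; a pair is a success when the early gene's
island is strictly smaller; equal sizes are excluded as sign-test zeros.
The p-value is the exact binomial upper tail P(Bin(n, ½) ≥ successes); a
success fraction above ½ is reported as direction `short_early`. This is
algebraically a paired-sample sign test, and the implementation is tested
for exact agreement with an independently coded one. Rank-matched pairing
is the reading consistent with a paired test; the cap defaults to the 250
top-ranked genes and is configurable.

Expression filters: CAGE peaks detected in ≤75% of samples are removed
(strictly-greater rule); RNA-seq genes need mean count > 5. Unmoderated
log2 fold changes ((mean+1)/(mean+1) ratios of replicate-averaged counts)
are provided for count tables; externally computed moderated fold-change
tables drop in interchangeably.

Differential response labels between unstimulated and stimulated cells
use a per-gene two-sided rank-sum test on library-size-normalized
expression with Benjamini–Hochberg control at FDR 0.05, the sign of the
mean log2 fold change splitting significant genes into up/down. The
noise-versus-response summary bins island sizes into 0.5-kb intervals
(mean CV2, or rCV2 on request, per bin and label; bins under 3 genes
reported missing), with one-tailed two-sample Kolmogorov–Smirnov tests of
the alternative that up-regulated genes are stochastically noisier than
down-regulated and unchanged genes, computed separately for the
non-island stratum.

## Synthetic data: what it emulates, and what it does not

`simulate_counts` draws mean normalized expression log2-normal(4, 1.5)
— a deep, read-level single-cell profile after depth and detection
filtering — and cell scaling factors log-normal (sd 0.25 on the log
scale, geometric mean 1). Counts are gamma-Poisson with dispersion

    phi_i = 0.3 * exp(N(0, 0.4)) + HV_i * (1.0 + Exp(1.5)),

a lognormal baseline around a floor of 0.3 plus, for hyper-variable (HV)
genes, a well-separated right-skewed excess. A gene is HV with baseline
probability 0.25; planted feature effects (island size, bivalency,
early-responder status) act on the log-odds of being HV. This encodes
"protective" regulatory features as reducing the chance that a promoter
is noisy — they cannot push noise below the sampling floor — and
reproduces the long-tailed rCV2 distribution seen in real data. It is
also the regime in which the absolute-residual statistic detects planted
effects with the correct sign (see above).

Annotations place one gene per fixed-width slot on synthetic chromosomes
(alternating strands), one island per island-positive gene centred on its
TSS; island sizes are log-normal (median ≈700 bp) truncated to
[200 bp, 20 kb]. Promoter GC tracks island status (0.65 vs 0.45 against a
0.40 background). Chromatin tracks draw per-window Gaussians: H3K4me3
modes at 0/4 (sd 0.5, 8 SDs apart), H3K27me3 at 0.2/3.0. Time-course
log2 fold changes are standard normal per comparison; a positive effect
adds `effect × (−z(log island size))` to the earliest comparison only.

Not emulated: read-level data, UMIs, doublets, batch effects, ambient
RNA, mean–dispersion coupling, spatial chromatin autocorrelation,
replicate-specific ChIP biases, or correlated gene programs. Passing
tests therefore demonstrate the statistical machinery under the stated
model, not robustness to those artefacts.

## Problem sizes and defaults

Simulation-based tests use 1,000–2,000 genes and 100–500 cells per seed,
with 25–200 seeds per property — sizes at which every acceptance check
completes in seconds on one core while the monitored rates (power ≥ 0.9,
type-I within [0.02, 0.08], classifier agreement ≥ 0.95) are stable
across seed choices. The demo bundle uses 600 genes × 120 cells with
island sizes capped at 8 kb so islands fit the 20-kb demo gene spacing.

All thresholds carry their standard defaults: cell depth 100,000;
detection 1% of cells; mu floor 0.1; chromatin multiplier 1.5; window
200 nt; promoter −1 kb/+500 bp; peak flank 500 bp; bin width 500 bp;
top 250 ranked genes; FDR 0.05; CAGE 75% detection; RNA-seq mean count 5.

## Known limitations

* The sign behaviour of screens on rCV2 depends on where genes sit
  relative to the fitted curve (see the structural note); effect types
  other than tail-membership shifts may be attenuated or sign-reversed.
* The deconvolution size factors are the simplified ring-pool form, not
  a full implementation with DE-gene trimming; strongly asymmetric
  differential expression between cell groups will bias them.
* The KDE threshold assumes a genuinely bimodal activating-mark
  distribution; shallow modes near the data boundary can be missed at
  the fixed 512-point grid.
* Exact ties in fold-change ranking are broken deterministically by gene
  identifier, which matters only for heavily tied inputs.
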