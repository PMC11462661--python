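# Methods

## Scope and data model

The pipeline starts from normalized beta values, not raw array
intensities: a beta matrix is a samples × probes `DataFrame` of
methylation fractions in [0,1] with `NaN` for explicitly missing entries.
Detection masking uses a strict inequality (entries with detection
p > 0.05 become missing; p = 0.05 is retained), probe filtering removes
cross-reactive probes, probes with a SNP at the target CpG, and probes on
chrX/chrY/chrM, and platform intersection/merging operates on the shared
probe set in lexicographic order so outputs are deterministic.  Retained
values always pass through bit-identically; filtering is idempotent.

Missing-value policy differs by stage on purpose.  Signature derivation
is probe-wise complete-case (a probe is skipped when fewer than half of
the extreme-quartile samples, or fewer than two per group, are observed);
CIMP calling drops any panel probe with a single missing value.  The
second rule is the published procedure for the CIMP panel; the first is
this package's choice for derivation, where sporadic masking would
otherwise discard usable probes.

## Quartile stratification and signature derivation

Samples are rank-ordered by cfDNA concentration (ascending; stable
secondary sort on sample identifier so ties are deterministic) and cut
into four groups whose sizes differ by at most one, the larger groups
first — 76 samples give 19 per quartile.  "Linear regression modeling" is
implemented as per-probe OLS of β on the binary indicator quartile-1 vs
quartile-4, which is algebraically the pooled-variance two-sample t-test;
no covariates are included because none are defined for the screen.  The
regression is run on β rather than M-values because every displayed
quantity downstream (cluster medians, heatmaps) is a β.  P-values are
corrected across all tested probes by Benjamini–Hochberg and the
signature keeps probes at FDR ≤ 0.01 (non-strict, so the set is closed
under exact ties).  Heatmap ordering sorts samples by cfDNA descending
and probes by mean β ascending, ties broken by identifier.

## Recursively partitioned beta-mixture model

The class-conditional model is a product of independent beta densities,
one per probe, with class-specific shapes (a_kp, b_kp); mixing weights
complete the mixture.  β values are clipped to [1e-6, 1−1e-6] before
any likelihood evaluation because the beta density diverges at {0,1}.

EM is initialised from 2-means on logit-β with a fixed seed
(responsibilities softened to 0.95/0.05).  The M-step computes the exact
weighted maximum-likelihood beta parameters per probe and class: a
method-of-moments start followed by damped Newton iterations on the
concave weighted log-likelihood (gradient in digamma, Hessian in
trigamma, step halving on any non-increase, convergence at gradient
∞-norm < 1e-10, cap 60 iterations).  An exact M-step makes the EM
log-likelihood provably non-decreasing, and the per-iteration trace is
stored and asserted monotone in the tests; a method-of-moments-only or
single-Newton-step M-step does not carry that guarantee, which is why
the iterated Newton refinement was adopted.  Convergence is declared at
relative log-likelihood change < 1e-6 with a 500-iteration cap;
non-convergence and degenerate classes (mixing weight < 1/n after up to
3 re-seeded restarts) are flagged on the result rather than raised.

Recursion: a node splits into two children when the 2-class BIC
(−2·loglik + [(k−1) + 2kp]·log n) beats the 1-class BIC on that node's
samples; recursion stops at `max_level`, on rejection, or below 4
samples.  The child of higher median β is labelled `L`, so leaf `rL` is
the expected *low*-release (hyper-methylated) cluster and `rR` the
expected high one.  Release-class prediction uses max level 1 (one
binary split, matching the two published clusters); CIMP uses max level
2 (≤ 4 leaves labelled CIMP-H, CIMP-L, CIMP3, CIMP4 by descending median
β; with fewer leaves, labels are taken from the top of that ordering).
Class naming depends only on medians, never on component order, so the
fit is label-swap invariant; exactly equal medians are treated as a
degenerate fit and raised for manual disambiguation.

Silhouette widths use Euclidean distance on the signature-probe β
vectors (the published metric is unstated; Euclidean on β is documented
as this package's choice).  Singleton clusters take width 0 by
convention.  The global ranking lists expected-high samples by
decreasing width, then expected-low by increasing width — most confident
high first, most confident low last.

## Association statistics

Spearman correlations (tie-corrected, two-sided) for cfDNA against
quantitative variables; Mann–Whitney for grouped variables, exact when
the smaller group has ≤ 8 observations and normal-approximate with tie
correction otherwise, two-sided by default (the direction of the
published tests is unstated; two-sided is the conservative reading).
Hypergeometric enrichment is one-sided over-representation
P(X ≥ k) — "enriched" is directional.  The aneuploidy score counts arms
with copy number ≠ 2 over a hard-coded canonical 39-arm set (p and q of
the 17 non-acrocentric autosomes, q only for 13/14/15/21/22); magnitude
of the deviation is ignored.  Significance symbols are * <0.05,
** <0.01, *** <0.005, **** <0.001 — the 0.005 three-star level is
unconventional but preserved as the screen's own convention.

## SNP-fingerprint identity

Alleles are called at fractional abundance strictly above 0.30;
positions with no surviving allele are dropped.  Two profiles are
compared over positions called in both, a position agreeing only when
the called allele sets are identical (partial overlap counts as
disagreement — the stricter, deterministic reading), and matched when
the concordance is strictly above 0.95.  The alternative reading —
95% agreement of allele-level fractions — was considered and rejected
as under-determined for multi-allele positions.

## ATAC post-processing

Coordinates are 0-based half-open.  Summits are extended symmetrically
to width 2·flank+1 (501 bp at the default); intervals overlapping the
blacklist or extending beyond [0, chrom_size) are removed, not clipped.
Scores are rescaled to sum to 1e6 per sample ("score per million").
Consensus building is iterative overlap resolution: keep the
highest-scoring peak, discard everything it overlaps, repeat — with
deterministic tie-breaks on (chrom, start, sample).  The promoter-overlap
test draws |accessible| genes uniformly without replacement from the
universe each iteration and records the percentage overlapping the
upregulated set; the closed-form hypergeometric expectation
100·|accessible|/|universe| is reported alongside for cross-checking.
The default of 10 iterations mirrors the original analysis but yields an
unstable SD estimate; ≥ 1000 iterations are recommended and the tests
validate the null mean at 10⁴.

## Synthetic cohorts

The generator emulates the screen's observed structure: a latent
standard-normal release propensity per sample drives (i) cfDNA,
log-uniform over 7.8–540.8 ng/µl via the probability transform (the
published range constrains only the range, so log-uniform is a modelling
choice); (ii) the binary release class (the lowest `class_fraction_low`
quantile is "low"); (iii) biology parameters through a Gaussian copula
with latent correlation r = 2·sin(π·ρ_s/6), the exact inverse of the
bivariate-normal Spearman map, so rank correlations hit their targets in
expectation — doubling time ρ = 0.72, cell loss ρ = 0.55, cycle
fractions −0.31/0.24/0.27/0.42 for 2N/S/4N/M.  Cycle fractions are
softmax-normalized jittered log-fractions, so they sum to one exactly
while remaining rank-coupled.  Probe values are Beta(m·φ, (1−m)·φ) with
per-probe means m and precision φ = 30, matching the mixture model the
clustering assumes; signature probes shift the low-releaser mean up by
Δβ (default 0.3, 145 probes); a CIMP panel carries four ordered class
means spaced by 0.2.  MSI and CIMP-positive labels follow a logistic
model with an odds multiplier (default 8) for low releasers.  Arm
profiles alter each of the 39 arms independently; SNP profile pairs
share exactly round(concordance·n) called genotypes; fragment-length
pairs are log-normal around 180 bp with the second sample shifted
shorter.  Everything is a deterministic function of the seed.

What the generator does *not* emulate: array noise structure (detection
failures are injected uniformly at random, real failures cluster),
probe–probe correlation (CpG islands are spatially coherent; probes here
are independent given class), batch effects, and biological overlap
between the signature and CIMP axes (planted independently here,
correlated in tumors).  Passing tests therefore demonstrate that the
statistical machinery recovers planted effects of realistic size at
screen-scale n, not that real methylomes will be classified with the
same accuracy.

## Problem sizes and defaults

Default cohorts are 76 samples × 2000 background probes (+60 CIMP
probes), the screen's sample size with a probe count large enough for a
meaningful multiple-testing burden while keeping a full pipeline run
under a few seconds.  Recovery properties are averaged over 5 seeds.
The pipeline's deterministic manifest records config hash, seeds and
per-file checksums; rerunning an identical configuration reproduces
byte-identical tables.

## Known limitations

- The beta-mixture EM assumes conditionally independent probes; strongly
  correlated probe sets overstate the effective likelihood and can
  over-split at larger depths.  BIC acceptance mitigates but does not
  remove this.
- Release-class naming requires exactly two top-level clusters; cohorts
  whose signature submatrix genuinely supports one or more than two
  clusters need manual handling.
- The exact Mann–Whitney branch enumerates the no-tie null; with heavy
  ties in small samples its p-values are approximate (as in the common
  implementations).
- The identity matcher compares called allele sets only; it does not
  model sequencing depth or allele-fraction uncertainty.
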