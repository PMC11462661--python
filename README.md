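# methylrelease

Why do some colorectal tumors shed almost no cell-free DNA (cfDNA) into the
blood, defeating liquid-biopsy assays?  Screens of colorectal cancer (CRC)
cell lines show that supernatant cfDNA spans roughly two orders of
magnitude across lines and tracks with slower cycling, higher cell loss and
— most strikingly — *lower* DNA methylation: CpG-island methylator
phenotype (CIMP) positive and MSI lines shed less, and demethylation
increases shedding.  `methylrelease` is an analysis toolkit for that line
of work: it derives a methylation signature that discriminates high from
low cfDNA releasers, predicts release classes in new methylomes by
recursively partitioned beta-mixture clustering, and carries the accessory
genomics around the screen (CIMP calling, association statistics,
arm-level aneuploidy scores, SNP-fingerprint identity checks, ATAC peak
post-processing).  A synthetic-cohort generator with known ground truth
makes every stage testable end to end without controlled-access data.

## What it computes

- **Signature derivation.** Samples are stratified into quartiles of
  cfDNA release; for each probe the beta value β ∈ [0,1] is regressed on
  the binary indicator of quartile 1 (lowest release) vs quartile 4
  (highest).  The slope's two-sided p-value (equivalently, the
  pooled-variance t-test) is Benjamini–Hochberg corrected, and probes at
  FDR ≤ 0.01 form the signature.  The effect size Δβ = mean β(low) −
  mean β(high) is positive for the observed direction "higher methylation,
  lower release".
- **Release-class prediction (RPMM).** On the signature submatrix, an EM
  fit of a two-class mixture of independent per-probe beta densities
  Beta(a_kp, b_kp) splits the cohort; splits are accepted only when the
  2-class BIC beats the 1-class BIC, recursively up to a maximum level.
  The higher-methylation cluster is labelled *expected-low* release.
  Samples are ranked by silhouette width (Euclidean distance on β).
- **CIMP calling.** A fixed CIMP probe panel (probes with any missing
  value dropped) is clustered with max level 2; the ≤4 leaves are labelled
  CIMP-H, CIMP-L, CIMP3, CIMP4 from high to low median methylation.
- **Associations.** Spearman correlations of cfDNA with doubling time,
  cell-cycle fractions, cell loss and the 39-arm aneuploidy score
  (+1 per non-diploid arm); Mann–Whitney tests for MSI/MSS and
  CIMP-positive vs negative; hypergeometric over-representation for
  contingency enrichments.
- **Accessory genomics.** ATAC summit extension to 501 bp,
  blacklist/bounds filtering, score-per-million normalization,
  iterative-overlap consensus peaks, Wilcoxon fragment-length comparison,
  and a permutation test for promoter-accessibility/expression overlap;
  SNP-fingerprint identity matching (alleles called above 30% fractional
  abundance, profiles matched above 95% position concordance).

## Worked example

The numbered scripts under `analysis/` run the whole screen on a
synthetic cohort and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_preprocess_beta.py
python analysis/03_derive_signature.py
python analysis/04_predict_release_class.py
```

which prints (seed 17):

```
cohort: 76 samples x 2060 probes
cfDNA range: 8.0-536.6 ng/ul
Spearman cfDNA~doubling time: 0.74 (target 0.72)
Spearman cfDNA~cell loss:     0.57 (target 0.55)
planted signature probes: 145
...
quartile sizes: {1: 19, 2: 19, 3: 19, 4: 19}
signature probes at FDR<=0.01: 152
recall of planted probes: 100.00%
...
clusters: {'expected-high': 38, 'expected-low': 38}
accuracy vs planted class: 100.00%
```

The cohort of 76 simulated lines spans the screen's ~2-log cfDNA range
with the stated rank correlations; the 19+19 extreme-quartile contrast
recovers all 145 planted signature probes (plus a handful of false
discoveries consistent with FDR 0.01), and the two-cluster beta-mixture
tree reassigns every sample to its planted release class.  Scripts 05–08
continue with CIMP calling, the association panel, ATAC post-processing
and identity matching.  The same flow is available programmatically:

```python
from methylrelease import PipelineConfig, run_pipeline, render_report

manifest = run_pipeline(PipelineConfig(output_dir="out", seed=17))
print(render_report("out"))
```

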