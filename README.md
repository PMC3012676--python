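# betam — Beta-value / M-value methylation metrics and titration evaluation

`betam` is an analysis package for Illumina Infinium-style DNA methylation
microarrays. Each CpG site is interrogated by a methylated/unmethylated probe
pair, and two summary statistics compete for the role of "the methylation
level":

* the **Beta-value**, the fraction of methylated signal

  $$\beta_i = \frac{\max(y_{i,\mathrm{meth}}, 0)}{\max(y_{i,\mathrm{unmeth}}, 0) + \max(y_{i,\mathrm{meth}}, 0) + \alpha}, \qquad \alpha = 100,$$

  bounded in [0, 1) and directly interpretable as a percent methylation; and

* the **M-value**, the offset-adjusted log-ratio of the two channels

  $$M_i = \log_2\!\frac{\max(y_{i,\mathrm{meth}}, 0) + \alpha}{\max(y_{i,\mathrm{unmeth}}, 0) + \alpha}, \qquad \alpha = 1,$$

  unbounded and approximately homoscedastic.

At high intensities the two are linked by a base-2 logit:
$M = \log_2(\beta / (1 - \beta))$, so $\beta$ of 0.2 / 0.5 / 0.8 equals $M$ of
−2 / 0 / 2. The Beta-value's variance collapses near 0 and 1 (severe
heteroscedasticity), which hurts t-test-based differential methylation
calling in exactly the ranges — nearly unmethylated and nearly fully
methylated sites — where most of the genome lives. The package quantifies
that trade-off with a titration benchmark: two samples mixed at known ratios
(100:0, 90:10, 75:25, 50:50, 0:100, with 2/2/1/1/2 technical replicates), true
positives defined as sites whose methylation profile has |Pearson r| > 0.8
with the mixing profile on both scales, and candidate lists scored by

* **TPR** = |TP ∩ detected| / |detected| and
* **DR** = |TP ∩ detected| / |TP|.

A synthetic Infinium-like simulator (Gamma-distributed channel intensities,
bimodal methylation prior, per-site intensity levels, per-array technical
factors) provides ground truth, so every claim is testable end to end.

## Layout

* `src/betam/` — the library: `core_metrics` (Beta/M and the logit link),
  `preprocess` (GenomeStudio-style TSV I/O, detection-p filter, simple
  scaling normalization), `synthetic_titration` (the simulator),
  `variance_diagnostics` (mean–SD bins, histogram modes), `differential`
  (Welch's t-test, range groups, ranking), `titration_evaluation` (TP set,
  TPR/DR curves, threshold guidance), `cli`.
* `analysis/` — numbered drivers that run the study: simulate → preprocess →
  variance diagnostics → differential analysis → titration evaluation,
  writing tables under `results/`.
* `betam` console script — `simulate`, `convert`, `diagnose`, `evaluate`
  subcommands over the same library.

## Worked example

```sh
python analysis/01_simulate.py
python analysis/02_preprocess.py
python analysis/03_variance_diagnostics.py
python analysis/04_differential.py
python analysis/05_titration_evaluation.py
```

prints (27,578 simulated sites, seed 2028):

```
beta extreme-bin vs middle-bin SD ratio: 0.231 (heteroscedastic: extremes compressed)
m max/min bin SD ratio: 1.050 (approximately homoscedastic)
...
TP set: 7025 of 27578 sites correlate with the titration profile (|r| > 0.8 on both scales)
   low:  beta TPR=0.713 DR=0.070 (n=693)  m TPR=0.807 DR=0.121 (n=1055)
middle:  beta TPR=0.982 DR=0.613 (n=4388)  m TPR=0.983 DR=0.561 (n=4009)
  high:  beta TPR=0.661 DR=0.054 (n=570)  m TPR=0.805 DR=0.124 (n=1082)
...
low-range DR retained at the comparable max threshold: beta 0.06 vs m 0.69
high-range DR retained at the comparable max threshold: beta 0.04 vs m 0.71
```

Reading these numbers: on technical replicates the Beta-value's median SD in
the extreme mean bins is less than a quarter of its middle-bin SD, while the
M-value's bin SDs vary by only 5% — the heteroscedasticity diagnostic. In the
low and high methylation ranges the M-value's ranked candidate lists achieve
both higher TPR and higher DR than the Beta-value's (in the middle range the
two are nearly tied, Beta with slightly higher DR and M with slightly higher
TPR). And imposing a constant minimum-difference threshold (Beta up to 0.25,
the comparable M range up to 2.0 — a non-log fold change of 1.32–2.64 for the
suggested M window 0.4–1.4) destroys the Beta-value's detection rate outside
the middle range (≤ 6% retained) while the M-value keeps ~70%.

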