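# Methods

## The two metrics and their link

For a CpG site with methylated and unmethylated probe intensities
$y_\mathrm{meth}$ and $y_\mathrm{unmeth}$ (possibly negative after background
adjustment; clamped at 0 before use):

* Beta-value: $\beta = \max(y_\mathrm{meth},0) \,/\, (\max(y_\mathrm{unmeth},0) + \max(y_\mathrm{meth},0) + \alpha)$ with offset $\alpha = 100$ by default. The
  offset regularizes dim probe pairs and keeps $\beta < 1$ strictly.
* M-value: $M = \log_2((\max(y_\mathrm{meth},0)+\alpha)/(\max(y_\mathrm{unmeth},0)+\alpha))$ with $\alpha = 1$ by default; the offset guarantees finiteness
  and damps the instability of log-ratios of near-zero intensities.

When total intensity is large both offsets are negligible and the metrics are
linked by the base-2 logit $M = \log_2(\beta/(1-\beta))$,
$\beta = 2^M/(2^M+1)$. The residual between `beta_to_m(compute_beta(x))` and
`compute_m(x)` is dominated by the offset mismatch on the dimmer channel,
$\log_2((u+100)/(u+1))$: about 0.14 at $u=10^3$ and 0.014 at $u=10^4$. The
agreement test therefore requires both channels above $10^4$ for its 0.02
tolerance.

Numerical choices in the metric layer:

* `m_to_beta` is evaluated as $1/(1+2^{-M})$ for $M \ge 0$ and
  $2^M/(2^M+1)$ for $M < 0$; the exponent is never positive, so the closed
  form cannot overflow at any finite $M$.
* `beta_to_m` is undefined at exactly 0 or 1. `compute_beta` with a positive
  offset never produces 1, but user-supplied tables can contain both
  boundaries, so a clip parameter (default $\varepsilon = 10^{-6}$) maps
  inputs into $[\varepsilon, 1-\varepsilon]$ first; passing `clip=None`
  raises instead.
* Round-tripping beta → M → beta is exact to $10^{-12}$. The reverse
  direction is limited by float64 itself: a beta near 1 stores
  $1 - 2^{-|M|}$ with absolute error up to $\epsilon/2$, which the logit
  amplifies to roughly $2^{|M|}\epsilon$ (about $10^{-8}$ at $M = 27$). No
  evaluation order avoids this, so the M-side round-trip tolerance is
  $10^{-6}$ over $|M| \le 30$.
* All operations are elementwise, preserve site/array order, and propagate
  missing cells (NaN) without imputation.

## Preprocessing

The on-disk format is a GenomeStudio-flavoured TSV (`TargetID` plus
`<array>.Methylated` / `.Unmethylated` / `.Detection_Pval` triplets). Two
standard steps are implemented:

* **Detection filter**: a site is removed when strictly more than a fraction
  (default 50%) of its arrays have detection p strictly greater than a
  threshold (default $10^{-4}$). "Worse" means larger, since Illumina
  detection p-values are small-is-good; the strict inequalities at both
  boundaries are a deliberate reading of "more than" and are parameterized.
* **Simple scaling normalization (SSN)**: each array is multiplied by one
  factor bringing its pooled (both channels, clamped at 0) mean intensity to
  the across-array grand mean. Sharing the factor between channels preserves
  within-array channel ratios, so M-values are invariant up to the offset
  term and Beta-values with offset 0 are exactly invariant. Color-balance
  checking and background correction, which full platform pipelines perform
  before scaling, are intentionally out of scope.

Filtering and normalizing do not commute in general (the factors are computed
on different site sets); the pipeline filters first.

## The synthetic titration experiment

The simulator emulates a HumanMethylation27-scale titration: defaults are
27,578 sites and the 8-array design of mixes 100:0, 90:10, 75:25, 50:50,
0:100 with 2/2/1/1/2 technical replicates.

* Per-site true methylation fractions $p_A$ are drawn from a bimodal prior —
  0.4 Beta(2, 20) (unmethylated mode), 0.4 Beta(20, 2) (methylated mode),
  0.2 uniform — chosen so the M-value histogram shows the platform's
  characteristic two modes, one negative and one positive.
* A configurable fraction of sites (default 0.3) is truly differential:
  $p_B$ is redrawn independently from the same prior; all other sites have
  $p_B = p_A$. The differential count is exact
  (`round(diff_fraction * n_sites)` sites chosen without replacement), not
  per-site Bernoulli, so truth denominators are deterministic.
* An array with mixing fraction $f$ sees $p = f p_A + (1-f) p_B$ — mixing
  acts on methylation fractions, which presumes the two samples contribute
  equal DNA amounts (titration protocols normalize concentrations before
  mixing).
* Channel intensities are independent Gamma variates with shape $k$ (default
  50, i.e. ~14% channel CV — under Gamma intensities the Beta-value is
  Beta-distributed) and means $T_i\,p\,s_a$ and $T_i(1-p)\,s_a$, where $T_i$
  is a per-site log-normal total-intensity level (mean 5000, log-SD 0.5;
  with these defaults ~99.7% of sites exceed total intensity 1000) and $s_a$
  a per-array log-normal technical factor with CV `replicate_cv` (default
  0.1) — the only between-array batch structure modeled.
* Detection p-values are fixed at $10^{-6}$ (everything simulated is real
  signal); an optional `failed_site_fraction` marks sites as failed for
  exercising the detection filter end to end.

What the simulator does **not** model: probe-type chemistry differences,
cross-hybridization, SNP-affected probes, dye or color-channel effects,
channel covariance, spatial artifacts, or biologically structured
differences (the real titration's gender/tissue/pathology sources collapse
into one redraw mechanism). Passing tests therefore show that the metric
comparison behaves as claimed under the idealized noise model that motivates
it, not that any particular real dataset will show identical numbers.

## Diagnostics

Per-site replicate means and SDs come from the technical replicate pairs:
within each group the mean and sample (n−1) SD are computed, then pooled —
SDs as the df-weighted root mean square, means unweighted. The pooling rule
is a package choice (multiple replicate pairs feed one diagnostic panel) and
is recorded with the outputs. Sites are ranked by mean and split into 20
equal-occupancy bins (earlier bins take remainders; ties in mean break by
site id), and each bin reports its median SD. Rank-binning makes the
site-to-bin assignment invariant under any strictly monotone transform of
the mean, which is what makes the Beta and M panels comparable.

Histogram bimodality is a descriptive indicator: counts in equal-width bins,
3-bin moving-average smoothing, local maxima counted as modes; no formal dip
test.

## Differential analysis and evaluation

Welch's unequal-variance t-test (two-sided, Welch–Satterthwaite df) gates
sites at p < 0.05 with no multiple-testing correction — deliberately the
non-stringent fold-change-ranking paradigm, so that metric differences, not
correction schemes, drive the comparison. Gated sites are ranked by absolute
mean difference; a minimum-difference threshold can be added. Both gates use
strict inequalities. Degenerate zero-variance-in-both-groups sites get p = 1
when the group means are equal and the zero-variance limit p = 0 (with a
warning) when they differ. On 2-vs-2 replicates Welch's test is inherently
conservative — even a reference implementation on ideal Gaussian data yields
an empirical type-I rate of ~0.024 at nominal 0.05, because the estimated df
falls below 2 — and the null-simulation test asserts exactly that
conservative regime.

Sites are assigned to range groups by the mean over the compared arrays
(which summary locates a site is genuinely open; the compared-group mean is
the minimal choice and is recorded): Beta low (0, 0.2), middle [0.2, 0.8],
high (0.8, 1); M low (−∞, −2), middle [−2, 2], high (2, ∞); boundaries
closed on the middle. Rankings and curves are computed within each group.

True positives require |Pearson r| > 0.8 against the titration profile on
both scales; replicate arrays enter with their mix's fraction repeated (n =
8 arrays, not 5 mixes), which changes the effective correlation null and is
recorded. Constant profiles are excluded as undefined (detected by an exact
range check, robust to 1-ulp centering noise). Top-N curves step by 50 and
always include a terminal point at the full list length. Threshold sweeps
report TPR as missing, not zero, when nothing is detected.

Turning points of the sweep are operationalized by plateau tolerances
(default 0.02 relative): the lower threshold is the last point where DR is
within tolerance of its value at 0, the upper the first point where TPR is
within tolerance of its maximum. If the TPR plateau starts before the DR
plateau ends the pair is flagged rather than reordered — on the simulated
data this overlap actually occurs, and it means any threshold between the
two keeps both statistics near their plateaus.

## Problem sizes and determinism

The analysis drivers and acceptance script use a platform-sized run (27,578
sites) for diagnostics and 10,000 sites with 30% differential for
evaluation; the TP-recovery check uses a low-noise setting (Gamma shape 200,
replicate CV 0.02) so that recovery reflects the criterion, not the noise
floor. All simulations are reproducible from a single integer seed through
one `numpy` Generator; TSV outputs use fixed 9-significant-digit formatting
so identical configurations produce byte-identical tables.

## Known limitations

* The TP definition inherits the titration design's blind spots: a site can
  be truly differential yet fail |r| > 0.8 under noise, and a null site can
  sneak in (~1.5% under defaults); TPR/DR are relative to this operational
  truth, exactly as in the benchmark design the package implements.
* The suggested-threshold procedure assumes the sweep is roughly
  rise-then-plateau / plateau-then-fall; pathological curves are flagged,
  not repaired.
* Range-group boundaries are fixed constants on each scale; sites near a
  boundary can change groups between scales because group assignment uses
  each scale's own means.
* No IDAT parsing, no quantile or other normalizations, no moderated
  (empirical Bayes) tests — the comparison targets the plain Welch workflow.
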