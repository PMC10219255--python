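# Methods

This note documents the models implemented in `threebias`, the parameter
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, the numerical decisions, and the known limitations.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The bias model

Coverage is assumed to decay exponentially with distance *d* from the 3′
end of a transcript: density ∝ exp(−d/τ), with a per-sample decay scale τ
(nt). Two closed forms follow:

- capture fraction of a transcript of length *L*:
  `B(L, τ) = (τ/L)(1 − e^(−L/τ))` — monotone decreasing in *L*,
  increasing in τ, → 1 as τ → ∞;
- fraction of a transcript's reads inside its 3′-terminal window of *W*
  nt: `w = (1 − e^(−min(L,W)/τ)) / (1 − e^(−L/τ))`.

The exponential form was chosen because it yields these closed forms,
which make both the generator and the window-counting correction testable
against Monte-Carlo and against each other. Real positional bias is not
exactly exponential (fragmentation, priming and mappability all
contribute); the model captures the essential monotone length dependence,
which is what produces the artifact.

Under a between-group τ imbalance, a null gene's expected count ratio is
`B(L, τ₁)/B(L, τ₂)`, a function of *L* — the length-correlated fold-change
artifact. For the 3′-window counts with L ≥ W the expected ratio is
`τ₁(1 − e^(−W/τ₁)) / (τ₂(1 − e^(−W/τ₂)))` — length-free, which is the
rationale for correction method 1. Transcripts shorter than *W* keep a
residual (but small, since B → 1 as L → 0) bias; this is the method's
intrinsic limitation, visible in the diagnostics as a nonzero residual
correlation.

## Synthetic data

`simulate_counts` draws `y_gs ~ NB(μ_gs, φ)` with
`μ_gs = s · e_g · B(L_g, τ_s) · 2^(x_s δ_g + a_s b_g)` where `e_g` is a
log-normal relative abundance, `x_s` the treatment indicator, `a_s ∈
{0, 1, 2}` the age index, and `s` scales the expected no-bias library to
`lib_size`. Windowed counts are Binomial thinnings of the same draws with
probability `w` (they share the biological noise of the full counts, as
reads from one library do). Defaults, chosen once as realistic for bulk
fly tissue and held fixed:

| parameter | default | rationale |
|---|---|---|
| `n_genes` | 2000 | desk-scale stand-in for the expressed transcriptome |
| `n_reps` | 3 | replication level of the emulated 36-sample design |
| `dispersion` φ | 0.1 | BCV ≈ 0.32, typical for bulk tissue with biological replicates |
| `baseline_mean_log`, `baseline_sd_log` | 3.0, 1.2 | a few-hundred-fold abundance range |
| `length_log10_range` | (2.5, 4.5) | ~300 nt–30 knt, the bulk of fly transcript lengths |
| `bias_tau` | 2000 nt | moderate decay; the real magnitude is unreported, so τ is the free calibration knob of the artifact |
| `lib_size` | 10⁶ | small but realistic library |
| `window_nt` | 1000 | the 3′-window default of the correction layer |

Lifespans are drawn from the Gompertz law `h(t) = a·effect·e^(bt)`
(defaults a = 10⁻⁴ d⁻¹, b = 0.12 d⁻¹ — median ≈ 55 d, plausible for adult
flies at 25 °C) by inverse-CDF sampling, rounded **up** to whole days
(deaths are observed at daily collection; no censoring). qPCR CT tables
are built so that `CT_target = CT_ref − ΔCT` with the injected log₂ fold
change added to ΔCT in the treated group, a per-sample plate offset shared
by all wells, and independent Gaussian well noise; the noise-free chain
therefore returns the injected value exactly.

What the generator does **not** emulate: isoform structure, GC or
position-specific sequence bias, sample-to-sample dispersion
heterogeneity, outlier genes, batch effects, correlated genes, censored
survival. Passing tests demonstrate correctness of the statistical
machinery under the stated model, not robustness to everything real data
do.

## The DE engine

- **Filtering**: keep a gene iff CPM > 1.0 (strictly) in at least
  ⌈0.5 · n_smallest_group⌉ samples.
- **TMM**: M-values are log₂ ratios of **raw counts** against a reference
  sample (the sample whose upper-quartile CPM is closest to the mean upper
  quartile); 30% two-sided trim on M, 5% on A; inverse delta-method
  variance weights; the factor is 2^(weighted mean), rescaled to geometric
  mean 1. Under this convention the factor absorbs depth *and*
  composition, and the effective library size is proportional to the
  factor itself — equivalent to the proportion-based formulation (where
  the factor multiplies library size) up to a constant common to all
  samples, which the equalization step removes. Two samples with identical
  composition and doubled depth get factors (1/√2, √2); identical samples
  get 1.
- **Equalization**: counts are divided by their relative scale and
  rescaled to its geometric mean, then **rounded** to integers — a
  proportional approximation to quantile adjustment that keeps the
  conditional likelihood and the exact test on integer counts.
- **Dispersion**: one common φ maximizing the conditional (per-gene,
  per-group totals) NB likelihood, optimized on log φ in [10⁻⁶, 10]
  (bounded Brent, xatol 10⁻⁶), clipped to 0 at the lower boundary. No
  tagwise shrinkage: a single φ keeps the exact test well-defined and the
  Poisson limit testable. The estimator needs ≥ 2 replicates in at least
  one group and is unbiased at the simulated scale (recovery tests).
- **Exact test**: conditional on a gene's total *z*, the treated-group sum
  follows `P(x) ∝ C(x+r_A−1, x)·C(z−x+r_B−1, z−x)` with `r_G = n_G/φ`;
  the two-sided p sums all splits with probability ≤ the observed one
  (tie tolerance 1 + 10⁻⁸, absorbing `gammaln` round-off at very large
  r). At φ = 0 the split law is exact binomial. LogFC is the log₂ ratio
  of group means of equalized counts with prior count 0.125 added to each
  mean (avoids infinities at zero counts).
- **FDR**: Benjamini–Hochberg step-up (statsmodels).

## Bias correction and consensus

Method 1 runs the full engine on the 3′-window counts (effective gene
length min(L, W) recorded). Method 2 assigns genes to equal-count bins on
log₁₀ length (ties broken by gene id; bins under 5 genes merged with a
neighbour), computes TMM within each bin, divides each gene's counts by
its bin's per-sample factor, then tests with a common dispersion and
applies the slope alignment to the resulting LogFC vector. Method 3 is
the alignment alone: OLS of LogFC on log₁₀ length, subtracting the
centred fitted component (mean preserved exactly, residual slope 0 to
machine precision, idempotent); its p-values are those of the uncorrected
test, since the transform touches only the fold changes.

Open design points, resolved as follows:

- the alignment operates on log₁₀ length (the zero-slope property is
  base-invariant; only the reported slope changes);
- alignment is applied inside methods 2 and 3 only, keeping the three
  methods as enumerated;
- "differently directed" means a strict sign conflict (min·max < 0);
  zeros agree with either sign;
- the consensus carries the chosen method's p-value, sets p = 1 for
  zeroed genes, and reruns BH across all genes — the consensus defines
  only a fold change, so a p-value convention was needed, and carrying
  the most cautious method's p preserves the all-three-must-confirm
  intent without discarding calibration;
- contrasts default to per-cell two-group comparisons (e.g. treated vs
  control within one sex–age cell, or old vs young within one sex–diet
  group), not a factorial model;
- LogFC is log₂ throughout; W defaults to 1000 nt and is configurable.

The three method results are intersected to their common gene set before
consensus (the corrections filter different count matrices, so coverage
can differ at the margins).

Because the consensus takes the *minimum*-magnitude estimate of three
noisy, positively correlated estimators, its fold changes are shrunk
toward zero relative to the truth (order-statistic bias), and its
discovery count is below each single method's — the price of the
conservative rule. The trade-off measured by the acceptance tests at the
defaults above: the rescue of a 4-fold τ imbalance removes somewhat less
than the hoped-for fraction of false discoveries (the linear alignment
cannot remove the curvature of the bias–length relation, and residual
same-sign agreement among methods lets a minority of short-gene false
positives through), and power retention under equal bias falls below the
targeted 70% at φ = 0.1 with 3 replicates (the chosen-method p is
typically the largest of the three). Both are properties of the method
at these study conditions, asserted honestly in the test suite rather
than hidden.

## Age trends, sets and overrepresentation

Trajectories are mean log₂(CPM + 0.5) per age over replicates of one
(sex, diet) group; the 0.5 prior keeps zeros finite. With ages coded
0, 1, 2 the OLS slope is (y₂ − y₀)/2, so the age fold change 2^(2b)
equals the fitted old/young ratio and is scale-equivariant. The
age-association p-value is taken from the old-vs-young consensus
contrast. Classification thresholds (p < 0.05, |log₂ FC| > 0.3, both
strict) follow the stated convention. Venn regions are the exact
inclusion–exclusion partition. ORA is the one-sided hypergeometric upper
tail per gene set (intersected with the universe) with BH across sets;
gene sets come from static GMT files, so results are version-stable.
Note that plain CPM trajectories are compositionally distorted when many
genes trend together — the injected fraction in recovery experiments is
kept small (3%) so the distortion stays well inside the assertion band.

## Survival battery

All individuals die under observation, so the Kaplan–Meier estimator
reduces to the empirical survival function and the log-rank test runs in
complete-data form with hypergeometric tie handling (heavy daily ties are
the norm); the implementation is `lifelines.statistics.logrank_test`.
The median test dichotomizes at the pooled median (lifespan > m vs ≤ m)
and applies the two-sided Fisher exact test — the construction used by
standard online survival-analysis services for median comparisons, since
the original convention is not fully specified. The Wang–Allison test is
the same construction at the pooled 90th-percentile threshold, ties
falling in "≤ threshold"; the sample maximum is reported descriptively
only. Bonferroni is min(1, m·p) per comparison. Degenerate 2×2 tables
(a zero margin) return p = 1 with a flag.

## qPCR

Technical replicates are averaged first; per-sample ΔCT = CT_ref −
CT_target, averaged arithmetically over reference genes (per-reference
values retained); −ΔΔCT = mean ΔCT(treated) − mean ΔCT(control).
Amplification efficiency is fixed at 2 (no Pfaffl correction), so −ΔΔCT
estimates log₂ fold change and is compared directly to RNA-seq LogFC;
sign agreement treats a zero on either side as agreeing (a zero estimate
makes no directional claim). No reference-gene stability statistic is
computed — excluding an unstable reference is a user decision.

## Problem sizes and numerical tolerances in the tests

Simulated experiments in the tests use 400–2000 genes, 3 replicates per
cell, and libraries of 10⁵–10⁶ reads; calibration properties use 2000
null genes (KS at α = 0.01; type-I band [0.03, 0.07]), 10 fixed seeds for
the artifact-rescue average, and 1000 fixed-seed Gompertz cohort pairs of
n = 150 for log-rank calibration (band [0.04, 0.07], with ≥ 80% power at
hazard ratio 0.5 over 200 runs). Oracle equivalences are exact-rational
enumerations (binomial split test, Fisher 2×2, hypergeometric ORA tails)
compared at relative tolerance 10⁻⁷–10⁻⁹; the slope alignment's residual
slope is required below 10⁻⁹. Worked examples (fold change 4; consensus
zeroing and minimum-magnitude selection; TMM √2 factors; BH by hand) are
asserted exactly or to 10⁻⁹.

## Known limitations

- A discrete conditional exact test is intrinsically mildly conservative
  (observed type-I ≈ 4.5% at nominal 5% under the default conditions);
  with enough null genes a KS test detects this super-uniformity — it is
  a property of the test family, not an implementation error.
- The linear slope alignment removes the first-order length trend only;
  the capture-ratio curve is nonlinear in log length, so extreme lengths
  retain residual bias.
- The consensus shrinks fold-change magnitudes (minimum of correlated
  noisy estimates) and loses power relative to any single method.
- Common dispersion only: no tagwise/trended estimation, no GLM, no
  batch covariates.
- 3′-window counting discards reads, inflating sampling noise, and does
  not correct transcripts shorter than the window.
- No censoring support in the survival battery; no efficiency-corrected
  qPCR quantification; no live pathway-database access (GMT input only).
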