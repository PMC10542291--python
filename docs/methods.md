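# Methods

## The relative-mutation-dosage model

A mother heterozygous (N/M) for a *GCK* variant contributes cfDNA with
variant-allele fraction 1/2. The placental (fetal) compartment, a fraction
*f* of total cfDNA, contributes 1/2 if the fetus is N/M and 0 if N/N, so the
plasma-wide variant fraction is

- θ(N/M, f) = 1/2,
- θ(N/N, f) = (1 − f)/2.

ddPCR partitions the sample into n droplets per channel. Under Poisson
loading at λ total target molecules per droplet, channel positives are

- k_v ~ Binomial(n_v, 1 − e^(−λθ)) (variant channel),
- k_w ~ Binomial(n_w, 1 − e^(−λ(1−θ))) (wild-type channel).

The duplex well is modelled as independent loading per target; a
double-positive droplet counts in both channels. The genotype posterior for
hypothesis h ∈ {N/M, N/N} marginalises the nuisance parameters:

P(h | data) ∝ π(h) ∫∫ P(k_v, k_w | λ, θ(h, f)) p(f) dλ df

with priors:

- π(N/M) = 1/2 by default (Mendelian expectation for a heterozygous ×
  wild-type cross); configurable.
- λ uniform on [10⁻⁶, 5] molecules/droplet — weakly informative, spanning
  clinical cfDNA concentrations.
- *f*: the fetal-fraction assay likelihood, a Normal(f̂, sd) truncated to
  (0, 0.5]; f̂ and sd come from the ZFX/ZFY or SNP assay via exact algebraic
  inversion (f = 2λ_Y/(λ_X + λ_Y) or f = 2λ_pat/(λ_pat + λ_ref)) with
  delta-method standard deviations. The common approximation
  f ≈ 2λ_ZFY/λ_ZFX is provided separately for cross-checks only.

A fetus is reported N/M when P(N/M | data) ≥ 0.95, N/N when ≤ 0.05
(both inclusive); anything between is inconclusive and triggers a repeat
sample.

### Numerical choices

The default inference is deterministic quadrature: trapezoid integration on
a 401 × 201 (λ × f) grid with log-likelihood evaluation and logsumexp
normalisation. The prior on λ is uniform over its full support, but the
quadrature nodes are placed adaptively over the pooled concentration MLE
± 8 posterior standard deviations (clipped to the support): at 20 000
droplets the likelihood occupies ~1% of the prior range, and fixed
equispaced nodes over [10⁻⁶, 5] would straddle it with too few points. The
f nodes likewise span f̂ ± 8 sd intersected with (0, 0.5]. With these grids
the two log-marginals are stable to well below 10⁻³, far tighter than any
decision threshold. A fetal-fraction likelihood with no mass in (0, 0.5]
raises a degenerate-input error; sd = 0 collapses f to a point (and f = 0
returns the prior, since the hypotheses are then indistinguishable).

The cross-check sampler is Metropolis-within-Gibbs over (h, λ, f),
vectorised across 8 chains: h is redrawn exactly from its full conditional
each sweep, λ and f by Gaussian random-walk Metropolis scaled to the data.
The reported probability is the Rao–Blackwellised average of
P(h = N/M | λ, f), which has far lower Monte Carlo variance than the
indicator average; convergence is declared when per-chain estimates agree
within 0.05. The sampler is fully seeded. Quadrature and MCMC agree within
0.02 on simulated data (tested), and quadrature is the default because it
is deterministic and ~50× faster.

Saturated wells (all droplets positive) are rejected rather than patched:
λ is unidentifiable there, and clinical inputs never approach saturation.

## QC and reporting workflow

QC gates are strict inequalities as specified clinically: fetal fraction
> 2% and fetus-specific droplet count > 10 (values exactly at the boundary
fail), plus assay specificity as a boolean input from the wet lab. A
pregnancy's outcome is one of: reported (earliest sample passing QC with a
conclusive call), no assay designable, QC failure with no repeat sample, or
below-reporting-threshold with no repeat sample. Turnaround is floor(days/7)
from receipt of the *first* sample to report issue, matching the whole-week
granularity of clinical reporting; the clock starts at the first sample even
when a repeat produced the report.

## Ultrasound arm

AC percentiles are Gaussian: percentile = 100·Φ((AC − mean(GA))/SD(GA)),
with mean and SD polynomial in gestational age and supplied as data (JSON).
A synthetic linear standard (mean 50 + 8·GA mm, SD 7% of mean, GA 14–42
weeks) is bundled so tests need no external file; real INTERGROWTH-21st
coefficients can be dropped in without code changes. Skewness (LMS)
corrections are out of scope unless encoded in the coefficients. Test
positivity (predicted N/M) is strictly below the 75th or 90th percentile; a
percentile exactly at the threshold is test-negative, since positivity is
defined as "<threshold" and equality is otherwise unassigned. The analysis
scan is the one in the inclusive 26–30-week window closest to 28 weeks,
ties to the earlier scan.

## Accuracy statistics

Positive class = N/M throughout. Proportions carry exact Clopper–Pearson
intervals; printed-style integer percentages use round-half-away-from-zero.
McNemar's test compares sensitivities (truth = N/M stratum) and
specificities (truth = N/N): exact binomial when discordant pairs < 25,
otherwise χ² = (b − c)²/(b + c) without continuity correction — the default
behaviour of the standard implementations of this test family; the cutoff
is configurable. PPV and NPV are compared with the generalized score
statistic for paired designs (a GEE working-independence score test of the
test-identity effect among positive — respectively negative — records, with
an empirical subject-clustered sandwich variance); the signed z statistic is
positive when the second test's predictive value is larger. ROC curves are
empirical; AUC equals the tie-corrected Mann–Whitney statistic. AUCs are
compared by a paired bootstrap stratified within genotype classes (default
2000 resamples, seeded), with a two-sided normal-approximation p on
delta/sd(bootstrap deltas). The Youden threshold maximises J = se + sp − 1,
ties toward higher sensitivity, returned as the midpoint between adjacent
distinct scores. The paired sample-size routine uses the standard
normal-approximation formula n = (z_{1−α/2}√ψ + z_{power}√(ψ − δ²))²/δ²
for discordance ψ and detectable difference δ; it is validated against a
simulation-based power oracle rather than against any single published n,
because published calculations rarely state ψ.

Feasibility quantiles are type-7 (linear interpolation); the rank-sum test
uses the exact distribution when both groups have n ≤ 10 without ties and
the tie-corrected normal approximation (no continuity correction) otherwise.
All tests are two-sided.

## The synthetic cohort generator

The generator is the forward model of everything above, fully seeded:

- Fetal genotype ~ Bernoulli(0.5); the confirmed genotype equals the truth
  (perfect reference standard; an error-rate knob exists, default 0).
- Referral GA ~ Uniform(8, 32) weeks; fetal fraction
  f = (3% + 0.5%/week × (GA − 10)) × LogNormal(0, 0.2), truncated to
  (0.2%, 40%) — a documented stand-in consistent with low-f QC failures at
  early gestation, not an empirical claim.
- ddPCR counts from the binomial/Poisson model at θ(genotype, f), λ = 0.2
  molecules/droplet, 20 000 droplets/channel; the fetal-fraction assay has
  λ_ch1 = λf/2 (fetus-specific) and λ_ch2 = λ(1 − f/2) (reference).
- AC percentile = 100·Φ(z) with z ~ Normal(μ_g, σ_g) per genotype. Both
  genotype models are solved in closed form from the two published
  classification proportions each (P(<75th) and P(<90th) per genotype):
  μ_NM ≈ 0.63, σ_NM ≈ 0.59, μ_NN ≈ 1.18, σ_NN ≈ 1.84. Matching all four
  proportions requires calibrating both location and scale for both
  genotypes; a unit-variance model for one genotype cannot reproduce the
  observed sensitivity at both thresholds simultaneously. The calibration
  is written alongside each generated cohort.
- Workflow: assay available with probability 42/43, pre-existing with
  probability 0.24; assay design Uniform(2, 8) weeks (0 if pre-existing),
  processing Uniform(1, 3) weeks. A first sample is reportable or not by
  *actually running the QC gates and the caller* on its generated counts —
  the laboratory's real decision rule — and an unreportable first sample
  triggers a repeat six weeks later with probability 0.9.

What the generator does **not** emulate: assay-specific amplification
biases, droplet-volume variation, maternal copy-number variation, mosaicism,
imperfect reference genotyping, and the real joint distribution of fetal
fraction with gestational age (unpublished). Passing tests therefore
demonstrate internal consistency of the model chain and correct
implementation of the statistics — not clinical performance on real
plasma.

## Problem sizes used in tests and the acceptance script

Caller calibration uses 200 simulated pregnancies per genotype at f = 10%;
fetal-fraction recovery 1000 replicates; the ultrasound-calibration check a
5000-pregnancy cohort; pipeline-level checks 20–43-pregnancy cohorts
(matching the study scale); the sampler cross-check 20 datasets. These sizes
put Monte Carlo error comfortably below the assertion margins while keeping
a full run in a few minutes.

## Known limitations

- The RMD likelihood treats channels as independent given (λ, f); true
  duplex wells share droplets, inducing a small negative correlation that
  is negligible at the occupancies involved (λ ≤ 0.5).
- The posterior assumes exactly two hypotheses; de novo variants, vanishing
  twins and placental mosaicism are outside the model.
- The growth standard is Gaussian per GA; heavy-tailed or skewed AC
  distributions require LMS-style coefficients, not supported.
- The published feasibility medians/IQRs and the continuous-score AUCs
  cannot be asserted numerically without individual-level data; they are
  mirrored qualitatively (direction of AUC ordering, rejection behaviour of
  the group comparisons).
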