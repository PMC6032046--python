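# Methods

## Model

Each SNP j in a nearly independent (LD-pruned) set carries an estimated
log odds ratio y_j under the additive allele-dosage model and a known
variance V_j. The marginal density is a two-component mixture: with
probability 1 − π the SNP is null and y_j ~ N(0, V_j); with probability
π it is disease-associated, its true effect β_j is drawn from an
unknown effect-size distribution g, and y_j | β_j ~ N(β_j, V_j). g is
modelled non-parametrically as a discrete distribution with masses
p_1 … p_B on a fixed grid of nonzero log-OR values, by default
−0.300 … 0.300 in steps of 0.005 with the zero point removed (B = 120;
odds ratios 0.74–1.35). Fixing the support and estimating only the
masses makes the non-null layer a B-component normal mixture with known
component densities, so the likelihood is concave in the full weight
vector (1 − π, π·p_1, …, π·p_B) and the maximiser is essentially
unique in that parametrisation.

Assumptions worth keeping in mind:

* independence across SNPs — defensible only after LD pruning, which is
  why pruning is part of the pipeline rather than an optional step;
* the asymptotic normal likelihood for each y_j with V_j treated as
  known;
* a shared g across the genome (no annotation-specific priors);
* effects oriented to a consistent allele (the derived allele when an
  allele map is supplied).

Weak identifiability is intrinsic to deconvolution: a larger π with
mass at very small |b| is hard to distinguish from a smaller π with
mass at moderate |b| when typical |b| is below the sampling standard
deviation √V_j. The likelihood surface has a long, nearly flat ridge
along this trade-off. Estimates of π are accurate at the scales where
the tests operate (see below); functionals that weight the ridge
asymmetrically (such as predicted future discoveries) inherit skew from
it, which is why interval estimates, not point estimates, are the
primary uncertainty statement.

## Estimation

(π, p) are estimated by EM. The E-step computes each SNP's posterior
responsibilities for the null component (weight 1 − π) and each grid
component k (weight π·p_k); the M-step sets every component weight to
its mean responsibility. Because the component densities never change,
the m × (B+1) log-density matrix is computed once — in log space with a
per-row max shift, since V_j ~ 10⁻⁴ drives tail terms below floating
underflow — and each iteration reduces to two matrix–vector products.

Plain EM is reliable here but slow in its tail (the flat ridge again),
so sweeps are wrapped by default in squared-extrapolation (SQUAREM)
cycles: two EM steps define a secant direction, the extrapolated point
is projected onto the simplex, and the cycle is accepted only if it
does not decrease the log-likelihood. The fixed point is unchanged, the
recorded likelihood trace stays monotone, and map evaluations drop
several-fold (578 versus 1572 at m = 100,000 in a representative run).
`EmConfig(accelerate=False)` restores plain EM; a test asserts both
reach the same optimum.

Numerical choices:

* stopping rule: relative log-likelihood change below 1e−8 (the ridge
  makes parameter-change rules misleading), capped at 10,000 map
  evaluations with a warning and `converged=False`;
* initialisation: a labelled multi-start family, π₀ ∈ {0.1, 0.01, 0.3,
  0.5} crossed with g₀ ∈ {uniform over the grid, triangular
  concentrated near zero}; the default single start is (0.1, uniform).
  With several starts the best final likelihood wins; near-ties
  (< 1e−6) resolve to the smaller π̂ for parsimony;
* π̂ = 0 leaves g unidentified; a uniform g is then reported;
* on instances small enough to check (m ≤ 50, B ≤ 4), the EM optimum
  agrees with an independent dense-grid-plus-polish maximiser to
  better than 1e−6 in log-likelihood.

## Prediction

Power of the two-sided Wald test at threshold z_c = Φ⁻¹(1 − p_c/2) for
a SNP with effect b and variance v is Φ(−z_c − b/√v) + Φ(b/√v − z_c);
at b = 0 it equals p_c exactly, a property the tests assert to machine
precision. The per-SNP rejection probability under the fitted mixture
is an exact finite sum over the grid (no quadrature), and the predicted
count among m* independent SNPs is K = m* × mean_j(P_j) with each V_j
rescaled by the ratio of summed inverse sample sizes. Only
1/n_r* + 1/n_s* enters, so curves are parametrised by the effective
number of cases n_e* = 2/(1/n_r* + 1/n_s*); required sample sizes are
found by bisection on the monotone curve to within one effective case,
then rounded up (default unit 1,000, configurable and recorded).

## Uncertainty

A parametric bootstrap: simulate y-vectors from the fitted (π̂, ĝ) at
the original V_j, refit, and summarise replicates — the standard error
of π̂ as the replicate standard deviation, intervals for K by the
order-statistic percentile rule (for n = 100 replicates at 95%, the 3rd
and 98th smallest). Replicate refits warm-start at the original fit;
this is recorded in the result metadata because it suppresses
initialisation-driven ridge wander and therefore gives the narrowest
defensible interval for K̂ itself.

When the quantity being checked is an *observed* significant count —
as in current-versus-future validation — the right target is a
prediction interval, not a confidence interval for the expectation:
the observed count fluctuates around K with approximately Poisson
noise even if (π, g) were known exactly. `bootstrap_k_ci(...,
include_count_noise=True)` therefore overlays a Poisson draw on each
replicate's K before taking percentiles, and `run_validation` uses
this interval when comparing against the future study's observed
count. Without the count-noise overlay, measured coverage of observed
counts was about 75%; with it, 18/20 truth replicates at the settings
below.

Failed replicate fits are dropped and counted, never imputed; more
than 20% failures is an error.

## Synthetic data

The generator emits exactly the structure the model assumes: Bernoulli
(π_true) non-null labels, effects drawn from a discrete g_true placed
on grid support (no jitter, so recovery targets are well defined),
variances from the standard asymptotic allele-count log-OR variance
V = [2 f (1 − f)]⁻¹ (1/n_r + 1/n_s) with allele frequencies f uniform
on (0.05, 0.5) — a common-variant spectrum chosen so that a 10,000 v
10,000 study has per-SNP standard errors of 0.014–0.032, comparable to
the effect sizes of interest. All draws are pure functions of
(scenario, seed) via fixed spawn keys, so frequencies, labels and noise
are individually reproducible. Block-LD fixtures (cliques with a
common r², nothing across blocks) exercise the pruning contract
without genotype data.

What the generator does **not** emulate: residual LD below the pruning
threshold, allele-frequency-dependent effect sizes, imputation error,
population stratification, or case ascertainment. Passing tests
therefore demonstrate correctness of the method under its own
assumptions — the appropriate target for a method package — not
robustness to the ways real consortium data violate them.

## Scales used by the test suite

Simulation sizes were chosen to exercise the statistically meaningful
regimes while staying desk-sized:

* recovery: m = 100,000 SNPs, 10,000 cases/controls, π ∈ {0.1, 0.2,
  0.4}, g at ±0.05, three seeds per scenario — the regime in which the
  estimator is accurate; mean π̂ within ±0.03 and ≥ 80% of ĝ's mass
  within ±0.01 of the true effects;
* prediction calibration: K from the true parameters against the mean
  observed count over 20 simulated futures at n_e* ∈ {10,000, 40,000};
* validation coverage: current 10,000 v 10,000 → future 20,000 v
  20,000 over m = 20,000 SNPs with a smooth polygenic truth (π = 0.25,
  non-null mass declining over |b| = 0.01–0.08), 20 truths, 30
  bootstrap replicates each. The smooth truth matters: under a
  two-point g, the non-parametric estimate necessarily smears mass
  around the spikes, and because power is convex in |b| over the
  relevant range, symmetric smearing inflates predicted future counts
  by ~10–30% at any m — a real property of point-mass architectures,
  not a bug, and one reason the spiky truth is used for recovery but a
  smooth truth for forward validation.

## Known limitations

* Effects outside the grid span (|log OR| > 0.3) are not representable;
  architectures with rarer, larger effects need a wider grid.
* The variance-rescaling projection assumes the future study mirrors
  the current one apart from size (same populations, phenotyping and
  imputation quality); predictions transfer only as well as that
  assumption holds.
* Predictions target the LD-pruned SNP set, not all genotyped SNPs;
  m* should be interpreted accordingly.
* The warm-started bootstrap understates initialisation-driven
  variability of the fit; interval widths for K̂ are conservative lower
  bounds in that specific sense.
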