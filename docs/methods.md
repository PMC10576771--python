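# Methods

## Model

twinace fits the correlated-factors parameterization of the multivariate
ACE model to wide twin-pair tables. Each of p traits loads on its own
additive-genetic (A), shared-environmental (C) and nonshared-environmental
(E) latent factor; same-type factors correlate freely across traits (rA,
rC, rE). On the phenotype scale this is equivalent to three p×p symmetric
component covariance matrices, and the expected covariance of the stacked
(twin 1, twin 2) trait vector is

    Sigma_z = [[A+C+E, k_z A + C], [k_z A + C, A+C+E]],

with k = 1 for MZ pairs and k = 1/2 for DZ pairs. Assumptions inherited
from the classical twin design: additivity of the genetic effect (the DZ
genetic correlation is fixed at exactly 0.5 — no dominance), equal
environments across zygosity, no assortative mating, no gene–environment
correlation or interaction, multivariate-normal phenotypes, and data
missing completely at random. Sex enters only through means and is removed
by residualization before modelling; sex-limitation variance structures
are out of scope.

## Likelihood and missing data

Model fit is full-information maximum likelihood: pair i with observed
subvector y_i (length k_i), expected subvector mu_i and submatrix Sigma_i
contributes

    k_i ln(2π) + ln|Sigma_i| + (y_i − mu_i)' Sigma_i^{-1} (y_i − mu_i)

to −2LL. Pairs are grouped by zygosity and missingness pattern, and each
pattern's sufficient statistics (count, sum, raw scatter) are cached, so an
evaluation costs one Cholesky per pattern regardless of sample size. A
non-positive-definite observed submatrix evaluates to +∞ (a finite 1e12
penalty inside optimizers). Pairs with every trait value missing are
dropped at load with a logged warning; they carry no information.

Degrees of freedom are counted as (number of non-missing trait values) −
(free parameters), the convention used in raw-data FIML fit tables.

## Parameterization and optimization

Free components are parameterized directly by their p(p+1)/2 symmetric
entries ("direct variance estimation"): diagonals are not squared or
Cholesky-factored, so component variances can go negative during and after
optimization and likelihood-ratio tests of dropping A or C are not biased
by a boundary. Only the total Sigma must be positive definite at the
reported solution; a violation flags the fit invalid rather than being
silently repaired. Standardized shares may therefore be reported slightly
negative; reports annotate, never truncate.

One mean per trait is shared across twins and zygosity groups (default;
residualized data are near-centered anyway). Optimization is L-BFGS-B with
numerical gradients followed by a Nelder–Mead polish, from a moment-based
start (within/cross-twin sample covariances solved through the MZ/DZ
expectation equations, E lifted to make both expected covariances positive
definite) plus seeded perturbed restarts (default 5; the tests and
acceptance study use a single start, which the moment initialization makes
reliable on well-conditioned data). Convergence tolerance is 1e-8 on −2LL.
Models whose identification needs the MZ/DZ contrast (A and C both free)
refuse to fit when a zygosity group is empty.

## Constrained saturated model

The descriptive baseline equates means and variances across twin order and
across zygosity, keeps within-twin covariances and the (symmetric)
cross-twin blocks free per zygosity: 2p + p(p−1) + p(p+1) free parameters.
Every ACE-family model is strictly nested in it (the full ACE model
additionally equates within-twin covariances across zygosity). The
published fit table this package's procedures parallel used a richer
saturated specification (its saturated df differs); the constraint set here
is the one that yields a single phenotypic correlation per trait pair, and
it is recorded in the fit's metadata. The reported phenotypic correlation
pools the two per-zygosity within-twin covariance blocks weighted by number
of pairs (variances are already equated); rMZ/rDZ come from the cross-twin
diagonal and CTCT correlations from the cross-twin off-diagonal.

## Confidence intervals

Profile likelihood (default): a scalar target is pinned and all other free
parameters re-optimized; the 95% bound solves profiled −2LL = min + 3.841,
located by geometric expansion and bisection (absolute tolerance 1e-4 on
the target). Raw entries, means, standardized shares and etiological
correlations are pinned by exact reparameterization (e.g. the pair (A_jj,
E_jj) becomes (share, total variance)); saturated-model correlations use
SLSQP equality-constrained profiling. A bound that cannot be bracketed
before the parameter domain ends is returned infinite and flagged
one-sided. The alternative is a pair-resampling bootstrap (resampling
within zygosity, percentile intervals, seeded; default 1000 draws).

## Decomposition

Standardized shares are X_jj / Sigma_jj and etiological correlations
X_jk / sqrt(X_jj X_kk) (undefined and flagged when a diagonal is ≤ 0). The
proportion of a phenotypic correlation due to component X is
rX sqrt(x_j x_k) / rph with the **model-implied** rph as the canonical
denominator: it makes the three shares sum to one exactly and reproduces
published share tables from their own printed inputs, which an observed
(saturated-model) denominator does not; shares over the observed rph are
emitted alongside when one is supplied. Shares are undefined (NaN, flagged)
where |rph| < 1e-6.

## Synthetic data generator

The generator draws pair vectors directly from the zygosity-appropriate
expected covariance built from standardized shares (a, c, e summing to one
per trait, e > 0 because E carries measurement error) and the rA/rC/rE
correlation matrices — distributionally identical to drawing the latent
A/C/E factors separately, and guaranteeing by construction that the
population covariance of simulated data equals the model's expected
covariance (verified by Monte Carlo at 100 000 pairs per group, tolerance
0.01 per entry). MZ pairs are same-sex; DZ pairs follow a configurable
same-/opposite-sex mix whose default matches the emulated study's
composition (145/284 MZ male/female, 138/227/342 DZ male/female/opposite).
Sex affects means only. Masking is completely at random — the regime under
which FIML is unbiased.

The study-like preset (`default_wellbeing_params`) uses three traits
(presence, happiness, life satisfaction) with a = (0.34, 0.42, 0.57),
c = 0, e = 1 − a, rA = (0.22, 0.36, 0.80) and rE = (0.15, 0.14, 0.47) at
429 MZ and 707 DZ pairs. What the simulator does **not** emulate: the 1–7
bounded ordinal scales of real questionnaire data (phenotypes are
unbounded normal; residualized real data are approximately so but skewed),
selection/attrition, assortative mating, and any non-MCAR missingness.
Passing recovery tests therefore demonstrates correctness of the estimator
under the model's own assumptions, not robustness to their violation.

## Model comparison conventions

AIC is reported as −2LL − 2·df (the df-based convention of published twin
fit tables) and BIC as −2LL − df·ln(n pairs); the standard −2LL + 2k and
−2LL + k·ln(n) forms are emitted alongside, since "size-adjusted" BIC
variants are software-specific and neither form is asserted against any
published BIC column. Selection requires both a nonsignificant LRT against
the full model (α = 0.05) and AIC within 10 of the minimum, then picks the
fewest-parameter survivor; exact ties fall to the documented ordering
ACE < AE < CE < E and are flagged. A negative chi-square below 1e-4 in
magnitude (optimizer noise) is clamped to zero with a warning.

## Numerical and testing choices

Problem sizes: Monte-Carlo agreement tests run at 100 000 pairs per group;
the recovery and profile-CI coverage studies use 100 seeded replicates at
the emulated study's 429+707 pairs; the model-selection preference property
uses 24 replicates against a ≥70% bound (the preference rate is empirically
much higher; the bound leaves honest Monte-Carlo room at that replicate
count). Round-trip CSV I/O is bit-exact (floats serialized by `repr`,
parsed with round-trip precision). Degenerate inputs — constant sex
covariate, empty zygosity groups, non-PSD correlation inputs, zero total
variance, near-zero rph denominators — raise typed errors or set flagged
NaNs rather than propagating garbage.

## Known limitations

No dominance (ADE), sex-limitation, longitudinal/simplex, or
ordinal-threshold liability models; no definition variables or moderators.
Profile CIs assume the chi-square(1) calibration of the profiled deviance,
which can be optimistic at boundaries (a share profiled near 0 or 1).
The bootstrap refits can fail on tiny resamples and are skipped with a
convergence error if fewer than 10 draws succeed.
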