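# Methods

This note records the statistical models implemented in `prevmap`, the
defaults they ship with and why, what the synthetic-survey generator does and
does not cover, and the numerical choices inside the samplers. Notation:
admin-1 areas are indexed by `a` (the survey's design stratification level,
crossed with urban/rural), admin-2 areas by `i`, clusters by `c`.

## 1. Direct estimation

For an area `A` the point estimate is the Hájek ratio

    p_hat = sum_{j in A} w_j y_j / sum_{j in A} w_j,

with `w_j` the design weights. Its variance uses stratified,
with-replacement-PSU Taylor linearisation: with cluster residual totals

    z_c = sum_{j in c} w_j (y_j - p_hat) / N_hat,      N_hat = sum_j w_j,

the variance is `sum_h n_h/(n_h-1) sum_{c in h} (z_c - z_bar_h)^2` over
strata `h` with `n_h` sampled clusters. Strata contributing a single cluster
to an area ("lonely PSUs") cannot supply a within-stratum spread; their
deviation is taken from the across-cluster area mean instead, a conventional
conservative fallback.

Uncertainty intervals are built on the logit scale: the delta method gives
`V_hat = var / [p_hat (1 - p_hat)]^2` for `theta_hat = logit(p_hat)`, and the
interval `expit(theta_hat ± z * sqrt(V_hat))` respects the (0,1) range.
Estimates are *degenerate* — unusable downstream as data — when the area has
no clusters, a single cluster, `p_hat` in {0,1}, or a linearised variance
below `1e-12` (all sampled clusters numerically identical).

## 2. Area-level (Fay-Herriot) model

Sampling model: `theta_hat_i | theta_i ~ N(theta_i, V_hat_i)` with `V_hat_i`
treated as known. Linking model: `theta_i = alpha + x_i' beta + u_i` with a
BYM2 random effect

    u = sigma ( sqrt(1 - phi) e_un + sqrt(phi) e_st ),

where `e_un` is IID standard normal and `e_st` follows an intrinsic CAR
(ICAR) on the adjacency graph, scaled so the geometric mean of its marginal
variances is 1 per connected component (sum-to-zero constraint within each
component; singleton areas receive only the unstructured part). The scaling
makes `sigma` interpretable as a total standard deviation regardless of graph
topology, which is what makes a generic prior on `sigma` defensible.

Priors: `sigma` gets a penalised-complexity (PC) prior — exponential with
rate `-log(alpha_0)/U`, default `U = 1`, `alpha_0 = 0.01`, i.e.
`P(sigma > 1) = 0.01`; on the logit scale a standard deviation of 1 across
areas is already a very large amount of between-area heterogeneity, so this
is weakly informative without being flat. `phi` gets the PC prior derived
from the Kullback-Leibler distance between the BYM2 field and its purely
unstructured base model, tabulated on a grid per graph; the rate is
calibrated over the whole real line so that `P(phi > 0.5) = 2/3`, mildly
favouring spatial structure (a positive-rate exponential cannot place 2/3
mass above the midpoint, hence the real-line calibration). Fixed effects get
`N(0, 31.6^2)` — effectively flat on the logit scale.

Fitting marginalises the latent Gaussian field analytically: an adaptive
random-walk Metropolis chain moves `(log sigma, logit phi)` under the
collapsed likelihood, and latent fields are recovered by exact conditional
(Matheron-style) draws given each hyperparameter state. Degenerate areas
enter without a likelihood term and are predicted from the linking model.
Hyperparameters can be pinned (`fixed_sigma`, `fixed_phi`,
`fixed_intercept`), which reduces the sampler to exact conjugate draws — used
by the tests to compare against closed-form normal-normal shrinkage.

### Phantom clusters

Areas failing the degeneracy screen at the modelling level are rescued by
injecting synthetic ("phantom") clusters carrying the parent admin-1 direct
prevalence and the area's (or parent's) average cluster weight-sum. An area
with no clusters receives a pair straddling the parent prevalence
(`round(n p) ± 1` successes) so that the resulting design variance is
positive; an area whose existing clusters all share one rate equal to the
phantom's would still be degenerate after a single matching phantom, so it
receives the straddling pair too. Phantom rows are flagged and excluded from
all reporting.

## 3. Cluster-level model

Per-cluster counts are beta-binomial,

    Y_c ~ BetaBinomial(n_c, p_c, d),   a = p(1-d)/d,  b = (1-p)(1-d)/d,

so `d` is the within-cluster correlation and `d -> 0` recovers the binomial.
The logit of `p_c` is built from a variant-specific linear predictor; the
variants form a nested family used for WAIC comparison:

| variant | linear predictor |
|---|---|
| `unstratified` | `alpha + u_i` |
| `nested_unstratified` | `alpha_a + u_i` |
| `stratified_nonnested` | `alpha + gamma R_c + u_i` |
| `stratified_nested` | `alpha_a + gamma R_c + u_i` |
| `stratified_nested_interaction` | `alpha_a + gamma_a R_c + u_i` |

with `R_c` the rural indicator and `u_i` BYM2 (or IID, or absent) at the
chosen area level. Covariates may enter at cluster or area level.

Priors mirror the area-level model for `sigma`, `phi`, and fixed effects.
`d` gets an exponential prior truncated to `(0,1)` calibrated so
`P(d > 0.5) = 0.1`: within-cluster correlations in household-survey
indicators are typically well below one half, and the truncated-exponential
shape shrinks toward the binomial base model in the same PC spirit. An
`intercept_prior="uniform-prevalence"` option puts a uniform prior on
`expit(alpha)`, giving an exact Beta-conjugate limit used for validation.

Sampling is adaptive Metropolis-within-Gibbs: per-area random-effect moves
are vectorised (all areas proposed in parallel, per-area likelihood deltas by
`bincount`); the structured component `s` is drawn exactly from its
constrained Gaussian conditional via a pre-computed eigendecomposition;
scalar hyperparameters use random-walk moves with Robbins-Monro adaptation
(target acceptance 0.44, adaptation during burn-in only). Two interweaved
joint moves break the strong centred-parameterisation coupling between the
field and its hyperparameters: a joint `(sigma, u) -> (c sigma, c u)` rescale
(the Gaussian prior ratio cancels the map's Jacobian, leaving the likelihood,
the `sigma`-prior ratio and `log c`), and a joint `(phi, u)` move that holds
the whitened residual fixed while translating the spatial mean. Both are
standard ancillarity-sufficiency interweaving ideas and leave the posterior
invariant.

Model comparison uses WAIC,
`-2 [ sum_c log mean_s L_cs - sum_c var_s(log L_cs) ]`, computed from stored
per-cluster log-likelihood draws; at least 100 draws are required since the
variance penalty is itself a Monte-Carlo estimate.

## 4. Aggregation

Model estimates are stratum-specific. Population prevalence per area is

    theta_i = (1 - q_i) expit(eta_i + gamma) + q_i expit(eta_i),

where `eta_i` is the urban linear predictor and `q_i` the urban share of the
*target population* in area `i`. `q_i` comes from gridded population
rasters: pixels are ranked by base-epoch population density and the top
pixels flagged urban until the national urban population share reaches the
supplied target (ties broken by pixel index; the threshold is clamped, with a
warning, if a single pixel overshoots); `q_i` is then the urban share of the
target-epoch population within each area. Rasters are stored as plain
ESRI-ASCII text grids. Pixel-level aggregation — `theta_i = sum_p q'_p
expit(eta_p)` over pixels with covariate rasters — is available for
fine-scale covariate models and reduces exactly to the stratified formula
when predictors are constant within strata.

## 5. Evaluation

The between-area variation statistic for a posterior field draw
`theta^(s)` is `v^(s) = (1/(M-1)) sum_i (theta_i - theta_bar)^2`; comparing
`v` between a fine-level model and a coarse-level model populated down to the
fine level screens for over-smoothing (the populated coarse field should show
*less* variation when genuine fine-level signal exists). Exceedance
probabilities are posterior tail masses per area. The default CV
usability threshold is 0.167 (a CV above ~1/6 means the 95% interval spans
roughly ±33% of the estimate). Comparison tables report correlations,
shrinkage slopes (regression of model on reference estimates), and interval
exclusion counts, keeping degenerate reference areas flagged rather than
silently dropped.

## 6. Synthetic surveys

The generator builds an enumeration-area (EA) frame on an admin-2 lattice:
per-admin-1 intercepts `alpha_a ~ N(alpha0, alpha_sd^2)`, a BYM2 admin-2
effect, an exact urban/rural contrast `gamma`, optional smooth covariate
surfaces, lognormal household counts, and Poisson eligible-population counts.
EA prevalences are exact (`expit` of the linear predictor), so area truths
are known eligible-weighted means. Defaults are national scale: 47 admin-1
areas, 300 admin-2 areas, ~430 EAs per admin-2, `alpha0 = 0.663`,
`alpha_sd = 0.3`, `gamma = -0.45`, `sigma = 0.3`, `phi = 0.5`, `d = 0.15` —
chosen as a realistic operating point for a DHS-style survey in a country of
this size and used as the study condition in the acceptance tests.

Surveys are stratified (admin-1 × urban/rural) two-stage samples: clusters by
systematic PPS on households with the standard recursive treatment of
certainty units (allocation proportional to stratum households with an urban
oversampling multiplier, default 2), then a fixed take of individuals per
cluster (default 25, capped at availability) with beta-binomial outcome
correlation `d` and optional non-response. Weights are inverse inclusion
probabilities with non-response inflation, so cluster weight totals equal
`N_c / pi_c` exactly.

Scope: the simulator is a *design* testbed, not a population model. It does
not simulate household rosters, multi-phase eligibility, geographic
displacement of cluster coordinates, or seasonal/temporal effects; the
lattice geometry is a stand-in for real boundaries, and the companion raster
generator produces desk-scale grids, not realistic population surfaces.

## 7. Numerical choices

- Beta-binomial log-pmf via `gammaln` differences; the `d = 0` limit is the
  exact binomial branch.
- ICAR scaling uses the pseudo-inverse of the component-restricted precision;
  eigendecompositions are cached per graph and reused by the exact Gibbs
  draws of the structured field.
- The PC prior on `phi` is tabulated on a 513-point grid from the KLD curve
  and interpolated; its normalisation and tail mass are verified by
  quadrature in the tests.
- Logit-scale computations clip nothing: degeneracy screens remove `p` in
  {0,1} before any logit, and validation errors are raised rather than
  silently repaired.
- All randomness flows through `numpy.random.default_rng` seeds carried in
  the spec objects; fits are reproducible and cluster-order invariant.

## 8. Limitations

- `V_hat_i` is treated as known in the Fay-Herriot model; no smoothing of
  design variances is implemented.
- The MCMC samplers are single-chain; diagnostics report effective sample
  sizes and warn when they are low, but no cross-chain convergence statistic
  (e.g. R-hat) is computed.
- WAIC is the only model-comparison criterion; no cross-validation.
- The urbanicity partition is a single national threshold on population
  density; countries with region-specific urbanisation definitions would need
  a different rule.
- Phantom-cluster rescue injects the parent-area prevalence with a fixed
  two-cluster spread; the resulting interval for rescued areas reflects that
  convention rather than real data.
- Aggregation assumes the fitted `gamma` (or `gamma_a`) transfers to the
  whole target population of each stratum; unmodelled within-stratum
  heterogeneity is not propagated.
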