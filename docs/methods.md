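# Methods

## Model

`sbglm` estimates task-activation amplitude fields on a triangulated
cortical surface. At each of the `N` data vertices the prewhitened BOLD
timeseries follows the linear model

    y_v = X_v beta_v + e_v,    e_v ~ N(0, sigma^2 I_T),

with `X_v` the expected response to each of `K` tasks (vertex-specific
after prewhitening). The classical benchmark fits this model
independently per vertex by least squares. The spatial Bayesian model
instead treats each task's amplitude image `beta_k` as a latent
Gaussian field with Matérn covariance of smoothness 1,

    cov(d) = sigma_k^2 (kappa_k d) K_1(kappa_k d),

represented as a Gaussian Markov random field through the SPDE/FEM
construction: with the lumped linear-FEM mass matrix `C` (diagonal;
vertex entry = one third of incident triangle area) and the cotangent
stiffness matrix `G`, the precision over mesh vertices is

    Q(kappa, tau) = tau^2 (kappa^4 C + 2 kappa^2 G + G C^{-1} G).

`kappa` is an inverse range (practical correlation range
`sqrt(8)/kappa` mm); `tau` scales precision (stationary marginal
variance `1/(4 pi kappa^2 tau^2)`). The SPDE smoothness exponent is
fixed at 2, the value for which Q has this closed form. The mesh may
contain padding vertices without data (medial wall, boundary ring); Q
is built over all mesh vertices and an indicator matrix `Psi` restricts
fields to data locations.

In the multi-run model, runs j = 1..J carry run-specific fields
`beta_{j,k}` that share the per-task hyperparameters `(kappa_k, tau_k)`
and the noise variance `sigma^2`; J = 1 recovers the single-run model.
Cross-run averages (or any weighted combination of run/task blocks) are
linear functionals of the joint Gaussian posterior and are available
exactly.

## Hyperparameter estimation

Because the likelihood and the field prior are both Gaussian, the
marginal posterior of `theta = (kappa_1, tau_1, ..., kappa_K, tau_K,
sigma^2)` is available in closed form through two sparse
factorisations per evaluation (prior precisions and per-run posterior
precisions). `fit_bayes_glm` maximises this log marginal posterior
(empirical Bayes) with L-BFGS-B in unconstrained log-parameters, two
deterministic starts (the second biased toward a smoother field), and
a 1e-6 objective tolerance; the field posterior is then the exact
conditional Gaussian at `theta_hat`. The only approximation relative to
full posterior integration over `theta` is the plug-in of `theta_hat`;
`theta_grid_sensitivity` evaluates the marginal posterior on a small
log-scale grid around `theta_hat` so the sharpness of that plug-in can
be checked per analysis. Hyperpriors default to wide log-Normal(0,
10^2) distributions on each `kappa_k` and `tau_k` and a Gamma(1, 5e-5)
prior on the noise precision; all are configurable and recorded in
output sidecars.

Sparse SPD factorisations use SuperLU in symmetric mode after a
reverse-Cuthill-McKee reordering with diagonal pivoting disabled,
giving an LDL^T-style factor that supplies log-determinants, solves and
exact GMRF sampling.

## Areas of activation

The excursion set at threshold `gamma` (percent signal change) and
level `alpha` is the largest vertex set whose joint posterior
probability of all amplitudes exceeding `gamma` is at least
`1 - alpha`. The set is grown greedily: vertices are ordered by
decreasing marginal exceedance probability `Phi((mu_v - gamma)/sd_v)`
(ties broken by vertex index) and the prefix extended while the joint
exceedance probability — estimated from joint posterior samples
(default 10,000; the binomial Monte-Carlo standard error is reported)
— stays at or above `1 - alpha`. Exhaustive subset search is
combinatorial; the greedy ordering is the standard concretisation and
is validated in the tests against exact orthant probabilities and
brute-force enumeration on small posteriors. A sign flag exposes
"deactivation" sets (amplitudes below `-gamma`). Because the joint
posterior is used, no multiplicity correction is applied; analysing
hemispheres separately at level `alpha` bounds whole-brain FWER at
`1 - (1 - alpha)^2`.

The classical benchmark tests `beta_v,k > gamma` per vertex with
`t = (beta_hat - gamma)/SE` on `T - K - 1` degrees of freedom (the
printed accounting, retained although centred designs fit no
intercept), followed by Bonferroni or Benjamini-Hochberg correction
within hemisphere; rank-deficient vertices are excluded from the
correction denominator and logged.

## Group inference

A group contrast is a weight vector `a` over (subject, run, task)
blocks — e.g. the all-subject cross-run average of one task puts
`1/(J*M)` on that task in every block — and the group field is
`beta_G = (a' (x) I_N) beta`. Subjects are combined as independent
given their fitted posteriors, each at its own `theta_hat`; the group
posterior is then Gaussian with block-wise mean, summed variances, and
exact joint sampling, and feeds directly into the excursion machinery.
This independence combination is an approximation to full joint
integration over shared hyperparameters and is flagged in output
metadata. Subjects with fewer runs than the contrast assumes are
supported by dropping absent run blocks (weights on absent runs are an
error). Classical group analysis averages subject coefficient maps and
uses a one-sample t-test against `gamma` with between-subject standard
errors (M - 1 degrees of freedom).

## Preprocessing

Order of operations: (1) scale each vertex to percent local signal
change, `100 (y - mean)/mean`; (2) build the task design by convolving
stimulus boxcars with a canonical double-Gamma HRF (response Gamma
shape 6/scale 1 s, undershoot shape 16/scale 1 s at ratio 1/6, 32 s
support, peak-normalised; peak ~5 s), max-scale each column to 1, then
centre; (3) jointly regress nuisance covariates — first-difference
temporal derivatives of the unscaled convolved regressors, linear and
quadratic drift, and (when supplied) motion parameters with their
first differences — from both data and design; (4) fit per-vertex
AR(6) models to the classical residuals by solving the Yule-Walker
Toeplitz system of biased sample autocovariances; (5) average AR
coefficients and innovation variances across runs and smooth them
along the surface with a 6 mm FWHM Gaussian kernel in graph-geodesic
distance (shortest paths along mesh edges, truncated at 3 sigma); (6)
prewhiten data and design per vertex with the banded lower-triangular
innovations-form square root of the AR precision (first p rows from
the Cholesky inverse of the leading AR covariance block), scaled so
whitened residual variance is 1 everywhere. The AR smoothing reuses the
package's own mesh kernel rather than an area-weighted implementation;
on well-resolved meshes the difference is small.

## Synthetic data

The generator emulates a motor-task protocol: TR 0.72 s, ~284 volumes,
five tasks by default, each presented as two 12 s blocks per run
preceded by 3 s cues, two runs per visit, two visits, configurable
subjects. Cue periods pace the timing but no cue regressor is generated
by default; callers wanting a cue column can add it as a task. True
fields are exact GMRF draws: each subject's field is a shared group
field (marginal sd `field_sd`, default 1% signal change) plus a
subject deviation (`subject_sd`), and each visit adds a visit deviation
(`visit_sd`), so the field-level ICC is
`subject_sd^2/(subject_sd^2 + visit_sd^2)` by construction. Noise is a
spatially varying AR(6) process (nonnegative base coefficients summing
to 0.68, modulated +-20% by a smooth Matérn field — nonnegative
coefficients with sum < 1 guarantee causality), scaled to a stationary
sd of `noise_sd` (default 1%), and a baseline of 1000 units is added so
percent-signal-change scaling is exercised. Everything derives from one
master seed.

Default mesh: a level-3 icosphere (642 vertices) scaled to 30 mm
radius, so the default `kappa = 0.3`/mm (range ~9.4 mm) is resolved by
~4 mm mesh edges; `make_mesh` itself defaults to a 100 mm cortical-
scale radius for standalone use. An optional `medial_wall` flag marks
a polar cap (icosphere) or the outer vertex ring (grid) as non-data
padding.

What the generator does not emulate: physiological (cardiac/
respiratory) noise, motion artifacts, multiband reconstruction
effects, inter-subject anatomical misalignment, or non-Gaussian
activation sparsity. Passing tests therefore demonstrate internal
consistency and calibration of the estimators under the stated model,
not robustness to those real-data complications.

## Verification protocol and problem sizes

The test-suite and `scripts/acceptance.py` computations use these
study sizes, chosen to make each check sharp at desk scale:

- Dense-oracle agreement of the Bayesian core: 100-vertex grid,
  T = 30, K = 2; sparse vs dense agreement required at 1e-6.
- SPDE-Matérn agreement: 20x20 unit-spacing grid, `kappa` set so the
  practical range is a quarter of the domain. At this resolution the
  lumped-mass GMRF inflates marginal variances ~10% uniformly (a
  discretisation effect; refining the mesh removes it, boundary
  padding does not), so the comparison is made on covariances
  normalised by the stationary Matérn variance, averaged within
  distance bins over vertex pairs at least one range from the
  boundary (the same rationale as the medial-wall padding layer);
  agreement within 10% is required at mid-range distances
  [range/2, 2 range].
- Hyperparameter/field recovery: 642-vertex icosphere, T = 200,
  K = 2, J = 2, kappa = 0.3, unit field sd, 1% AR(6) noise; 20
  replicates in the tests (10 in the acceptance script).
- Null calibrations: 500 white-noise replicates (T = 200, N = 300)
  for the Bonferroni classical GLM; 200 (tests) / 100 (script) full
  Bayesian fits on 36-vertex null studies for excursion sets.
- ICC recovery: 45 subjects, 2 visits, T = 400, noise sd 0.3% — the
  low measurement noise isolates the generator's field-level variance
  split (subject sd 1%, visit sd 0.5%, split 0.8), which is what the
  check targets; residual deviation reflects the sampling variability
  of one 45-subject field realisation.
- Multi-run efficiency: 162-vertex icosphere, T = 150, 20 replicates.

Numerical choices: optimisation bounds of +-6 log-units around the
scale-aware start (prior range a quarter of the effective domain
length, unit prior marginal variance, unit noise variance); excursion
ties broken by vertex index; excursion sets report the last prefix
whose estimated joint probability is >= 1 - alpha; ICC uses population
(1/n) variances and truncates negative between-subject variance at
zero, returning missing when total variance is zero; Dice of two empty
maps is missing, flagged.

## Known limitations

- Plug-in empirical Bayes understates hyperparameter uncertainty
  relative to full integration; the grid-sensitivity helper quantifies
  but does not remove this.
- Graph-geodesic distances overestimate true geodesics off the edge
  directions of coarse meshes (visible on regular grids along the
  unsplit diagonal); smoothing kernels inherit this anisotropy.
- The greedy prefix excursion construction is a heuristic for the
  "largest set"; it is exact for exchangeable posteriors and validated
  against enumeration on small problems, but global optimality is not
  guaranteed.
- The independence-across-subjects group combination ignores shared
  hyperparameter uncertainty.
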