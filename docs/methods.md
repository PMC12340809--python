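# Methods

## Model

`tpclust` performs outcome-guided subtyping: it partitions subjects into K
latent subtypes using both a high-dimensional omics profile and the shape of
a longitudinal outcome trajectory, while estimating subtype-specific,
*time-varying* covariate effects.

For subject i with omics vector g_i = (1, g_i1, ..., g_iQ)', static
covariates x_i = (1, x_i1, ..., x_iP)', longitudinal covariates v_im(t) and
outcomes y_i(t_ij), j = 1..T_i, the observed-data likelihood is the mixture

    L = prod_i sum_k pi_ik(gamma) f_k(y_i | x_i, v_i; theta_k, xi_k, sigma_k),

with two sub-models:

* **Membership prior** — multinomial logistic in the omics:
  pi_ik = exp(g_i' gamma_k) / sum_r exp(g_i' gamma_r), with gamma_1 = 0 fixed
  for identifiability (subtype 1 is the reference).
* **Longitudinal outcome** — conditional on subtype k,
  y_i(t_ij) = alpha_ik + sum_{p=0..P} x_ip beta_pk(t_ij)
  + sum_m v_im(t_ij) rho_mk(t_ij) + eps_ijk, with alpha_ik ~ N(0,
  sigma_alpha_k^2) a subject random intercept and eps ~ N(0, sigma_eps_k^2).
  beta_0k(t) is the subtype mean trajectory.  The induced within-subject
  covariance is compound symmetric, sigma_eps^2 I + sigma_alpha^2 11', and is
  always handled through the rank-one (Sherman–Morrison) identity, so
  per-subject likelihood evaluations cost O(T_i).

Every smooth effect is expanded in one shared B-spline basis b(t) (default:
cubic, nb = 8 basis functions, equally spaced interior knots over the
observed time range), so beta_pk(t) = b(t)' theta_pk and rho_mk(t) = b(t)'
xi_mk.  The basis is deliberately generous; smoothness is controlled by a
roughness penalty rather than by the knot count.

## Penalties

The penalized objective subtracts from the (profiled) log-likelihood:

* a **sparse group lasso** on gamma —
  lambda1 sum_{k,q>=1} |gamma_kq| + lambda2 sum_l ||gamma_{A_l}||_2,
  where each A_l collects the gamma entries (all subtypes) of the features in
  pathway l.  Intercepts are never penalized.  The group term removes whole
  uninformative pathways; the elementwise term prunes individual features
  (including features in no pathway);
* a **roughness penalty** on every curve — nu_p theta_pk' Q theta_pk and
  kappa_m xi_mk' Q xi_mk with Q_rs = integral of b_r'' b_s''.  Q is computed
  exactly by per-interval Gauss–Legendre quadrature; its null space is the
  affine curves, so straight-line effects are never shrunk.  One nu_p (kappa_m)
  is shared across subtypes.

## Estimation: modified EM

Treating subtype labels z_i and random intercepts alpha_ik as missing data:

* **E-step.**  Posterior weights w_ik proportional to pi_ik f_k(y_i)
  (computed with per-subject log-sum-exp), and the conditional intercept
  moments given membership, a_ik = E[alpha_ik | y_i, z_ik = 1] (the
  compound-symmetry BLUP) and a2_ik = E[alpha_ik^2 | y_i, z_ik = 1].  The
  weights w_ik enter the M-steps as the diagonal of W_k.  We use the exact
  conditional moments here: a variant that additionally multiplies the
  intercept moments themselves by w_ik was evaluated during development and
  produces a systematically biased fixed point whenever memberships are soft
  (measured on scenario-1 fits: roughly double the coefficient-curve RMSE and
  distorted sigma_alpha), which invalidates the bootstrap bands; the exact
  moments are required for the nominal ~95% coverage this model family is
  designed to deliver.
* **M-step, gamma.**  Weighted multinomial logistic regression with the
  sparse-group-lasso penalty, solved by FISTA with the exact SGL proximal
  operator (elementwise soft-threshold, then blockwise group shrinkage),
  warm-started across EM iterations; a fixed global Lipschitz bound
  0.5 lambda_max(G' Omega G) with a monotone step-halving safeguard.  Solver
  output below 1e-8 in magnitude is an exact zero; the selected set S is the
  features with any nonzero gamma entry.  Overlapping pathway groups are
  shrunk sequentially (exact for disjoint groups, the common case).
* **M-step, curves.**  For each subtype the spline coefficients solve the
  weighted, roughness-penalized normal equations
  (X' W_k X + U)^{-1} X' W_k (Y - alpha_k) in closed form, where U is the
  block-diagonal roughness matrix and alpha_k stacks the a_ik.
* **M-step, variances.**  Closed-form updates: sigma_eps_k^2 is the
  W_k-weighted mean of (residual^2 + a2 - a^2) (the conditional-variance
  correction), sigma_alpha_k^2 the weighted mean of a2; both SDs floored at
  1e-6 to avoid degeneracy.

Convergence is declared when the relative change of the penalized
observed-data log-likelihood falls below `tol` (default 1e-6, max 200
iterations).  The EM ascent check in the test suite uses relative slack
1e-8 * (1 + |objective|), since an absolute 1e-8 is below float64 resolution
for objectives of magnitude ~1e3.

**Initialization and restarts.**  Initial hard labels come from K-means on
per-subject (level, slope) summaries of the outcome, softened to 0.9 / 0.1
one-hot weights; `n_restarts` runs keep the best final penalized objective.
**Empty components** (no subject above weight 1e-4) are re-seeded from the
most ambiguous subjects; if a component collapses repeatedly, the fit is
retried with K-1 and a warning.  **Label order** is canonicalized by
descending time-averaged mean trajectory, so subtype 1 is always the
highest-outcome ("resilient-like") component and gamma_1 = 0 is restored by
re-gauging after permutation.

## Tuning

Relaxed-lasso cross-validation: for each candidate (lambda1, lambda2, nu,
kappa, K), the penalized model is fitted once on the full data to get S;
within each of the (default 5) subject-level folds the model is refitted on
the training subjects using only S and *no* sparsity penalties (removing
lasso shrinkage bias; roughness retained; coefficients outside S pinned at
zero), and the held-out observed negative log-likelihood is the loss.
`suggest_penalty_grid` builds scale-aware lambda grids as fractions of the
data-driven score maxima at gamma = 0 (the glmnet-style lambda_max
convention), so grids need no hand calibration.

## Inference: multiplier bootstrap

Each replicate draws iid Rademacher u_i and re-maximizes the objective with
every subject's contributions weighted by (u_i + 1) in {0, 2}: the logistic
term restricted to the selected set S (no sparsity penalties — the relaxed
form) and the longitudinal term with roughness retained.  Refits are
warm-started at the original estimates (a single EM run, max 50 iterations)
and re-aligned to the original fit by nearest-mean-curve assignment
(Hungarian matching on integrated squared distance).  Pointwise bands are
estimate(t) + z_{alpha/2} s(t), estimate(t) + z_{1-alpha/2} s(t) with s(t)
the replicate SD — centered at the original estimate, not the bootstrap
mean.  Degenerate draws (all weights zero) and collapsed refits are dropped
and counted in the reported effective B (default B = 200 for applied use;
the simulation studies use B = 100).

## Synthetic-data generator

`simulate.scenario_preset` reproduces the two simulation designs: K = 3
subtypes, P = 2 static covariates (one binary, one standard normal), M = 1
longitudinal covariate (standard normal per visit); scenario 1 has Q = 110
features in 6 pathways (one all-informative pathway of 10, five noise
pathways of 20), scenario 2 has Q = 520 in 7 pathways (two informative of
10, five noise of 100).  Features are standard normal; subtype labels are
drawn from the multinomial logistic model with gamma_true loading 1.2 on the
informative features (subtype 2 on the first half, subtype 3 on the second,
intercepts -0.9 for roughly 40/30/30 frequencies) — so conditional on
subtype the informative features have class-shifted means.  Mean curves and
static effects are linear combinations of a cubic 6-function B-spline on
[0, 1] with visibly separated trajectories (stable-high / late-decline /
rapid-decline); rho_1k(t) is linear for two subtypes and quadratic for the
third; T_i ~ Uniform{4..8} visits at Uniform(0, 1) times; sigma_eps =
sigma_alpha = 0.5.  All truths are fields of `SimConfig` and can be replaced
wholesale.

Each subject is drawn from its own seeded substream keyed by (seed, index),
so datasets are *nested* across sample sizes at a common seed — a
common-random-numbers design that makes paired sample-size comparisons
(e.g. the IMSE consistency check) low-variance.

What the generator does *not* emulate: correlated omics features, non-Gaussian
noise, informative visit schedules, outcome-dependent dropout, and
measurement error in covariates.  Passing tests demonstrate correctness of
the estimator and its inference under the stated model, not robustness to
those violations.

## Evaluation metrics

IMSE (trapezoid rule on a 100-point grid, components aligned to truth by
nearest mean curve), empirical pointwise coverage over (replicate, grid
point) pairs, FDR/TDR of the selected set (FDR of an empty selection is
defined as 0), interval-averaged effects (normalized integrals with boundary
interpolation), odds ratios exp(gamma_kq) vs the reference subtype, and the
adjusted Rand index for label agreement.

## Problem sizes used by the shipped studies

The acceptance script and end-to-end tests run scenario 1 with n = 500,
20 replicates and B = 100 bootstrap refits for coverage; 10 paired
replicates at n in {500, 1000} for the IMSE comparison; 10 replicates at
n = 1000 for selection.  Penalties are tuned once by 3-fold relaxed-lasso CV
on the first replicate (two stages: lambdas at fractions {0.3, 0.1, 0.03} of
lambda_max, then shared nu = kappa over {1, 0.1, 0.01}) and reused across
replicates.  These are the package's default desk-scale study sizes.

## Known limitations

* Single continuous outcome; no multivariate or non-Gaussian outcomes.
* Random intercepts only (no random slopes or general covariance).
* K must be pre-specified or chosen by CV; no information-criterion or
  Bayesian selection.
* Pointwise (not simultaneous) confidence bands; no inference on gamma.
* The two-stage tuning (selection on the full data, relaxed refits within
  folds) carries a mild optimistic bias, accepted for tractability.
* Curves are never extrapolated: evaluation outside the training time range
  clamps to the boundary with a warning.
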