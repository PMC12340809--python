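# tpclust

Outcome-guided molecular subtyping from longitudinal trajectories.

`tpclust` is for studies that follow subjects over time (e.g. aging cohorts
with repeated cognitive assessments) and also profile them molecularly (e.g.
post-mortem transcriptomics). It answers three questions jointly, in one
probabilistic model:

1. **Which latent subtypes exist?** Subjects fall into K subtypes whose
   outcome trajectories differ in shape, not just level.
2. **Which omics features define them?** Membership probabilities are
   multinomial-logistic in a high-dimensional feature vector, with a sparse
   group lasso (pathway-level + feature-level sparsity) selecting the
   informative features.
3. **How do risk-factor effects change with time within each subtype?**
   Covariate effects are smooth functions of time, not constants.

## Model

For subject i with omics g_i, static covariates x_i, longitudinal covariates
v_im(t) and outcomes y_i(t_ij):

    P(z_ik = 1 | g_i)  =  exp(g_i' gamma_k) / sum_r exp(g_i' gamma_r),   gamma_1 = 0,

    y_i(t_ij) | z_ik=1 =  alpha_ik + sum_{p=0..P} x_ip beta_pk(t_ij)
                          + sum_m v_im(t_ij) rho_mk(t_ij) + eps_ijk,

with random intercept alpha_ik ~ N(0, sigma_alpha_k^2) and noise
eps ~ N(0, sigma_eps_k^2). Each beta_pk(t) and rho_mk(t) is a B-spline
expansion b(t)'theta with a roughness penalty theta'Q theta (Q = integrated
squared second derivative, null space = straight lines). Estimation is a
modified EM algorithm: exact posterior E-step (log-space mixture weights,
Sherman–Morrison compound-symmetry likelihoods), a proximal-gradient
sparse-group-lasso M-step for gamma, and closed-form penalized
weighted-least-squares and variance M-steps. Penalties are tuned by
relaxed-lasso cross-validation; pointwise confidence bands for every
time-varying effect come from a multiplier (Rademacher-weight) bootstrap.
See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
import tpclust as tp

sim = tp.scenario_preset(1)                      # K=3, 10 informative + 100 noise features
study, truth = tp.generate(sim, n=500, seed=7)   # 500 subjects, 4-8 visits each

config = tp.FitConfig(K=3, lambda1=20.0, lambda2=30.0, nu=0.1, kappa=0.1, seed=0)
fit = tp.fit_em(study, config)
print(f"converged: {fit.converged} after {fit.n_iter} iterations")
print(f"selected features: {fit.selected_features.tolist()}")

posterior, labels = tp.posterior_assign(fit, study)
print(f"subtype sizes: {np.bincount(labels).tolist()}")
print(f"ARI vs generating labels: {tp.label_agreement(truth['z'], labels):.3f}")

fdr, tdr = tp.fdr_tdr(fit.selected_features, truth["informative"])
print(f"selection FDR: {fdr:.2f}, TDR: {tdr:.2f}")

bands, eff_B = tp.bootstrap_bands(study, fit, config, B=100, alpha=0.05, seed=0)
band = next(b for b in bands if b.kind == "beta" and b.index == 0 and b.subtype == 2)
mid = len(band.t_grid) // 2
print(f"subtype-3 mean trajectory at t=0.5: "
      f"{band.estimate[mid]:.2f} (95% CI {band.lower[mid]:.2f} to {band.upper[mid]:.2f})")
```

prints

```
converged: True after 46 iterations
selected features: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9]
subtype sizes: [187, 174, 139]
ARI vs generating labels: 0.909
selection FDR: 0.00, TDR: 1.00
subtype-3 mean trajectory at t=0.5: -0.80 (95% CI -0.94 to -0.65)
```

The fit recovers exactly the 10 generating informative features (TDR 1.00 at
FDR 0.00), reassembles the three subtypes almost perfectly (adjusted Rand
index 0.91 against the generating labels), and the bootstrap band around the
rapid-decline subtype's mean trajectory at mid-study excludes the other
subtypes' trajectories by a wide margin.

Subtypes are always reported in descending order of their time-averaged mean
trajectory, so subtype 1 is the most preserved ("resilient-like") group and
odds ratios `tp.odds_ratios(fit)` are relative to it.

## Command line

The same pipeline is scriptable:

```
tpclust simulate --scenario 1 --n 500 --seed 7 --out data/
tpclust fit      --data data/longitudinal.csv --static data/static.csv \
                 --omics data/omics.csv --gmt data/pathways.gmt \
                 --long-covs v1 --config cfg.yaml --out fit.json
tpclust tune     ... --out cv_table.csv
tpclust bootstrap ... --fit fit.json --B 200 --alpha 0.05 --out bands.csv
tpclust evaluate --truth data/truth.json --fit fit.json --out metrics.csv
```

Inputs are plain delimited text (long-format longitudinal table,
cross-sectional covariate table, subjects x features omics matrix) plus a
GMT pathway file; fits serialize to a single JSON document.

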