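"""M-step solvers and the modified EM driver."""

import numpy as np
import pytest
from scipy.optimize import minimize

import tpclust as tp
from tpclust.em_fit import (
    _init_weights,
    m_step_gamma,
    m_step_longitudinal,
    m_step_variances,
)
from tpclust.model_core import PenaltySpec, assemble_designs, e_step, subtype_prior
from tpclust.splines import build_basis, eval_curve, roughness_matrix

from conftest import make_tiny_study


# ---------------------------------------------------------------------------
# gamma M-step
# ---------------------------------------------------------------------------


def test_gamma_fully_shrunk_limit():
    rng = np.random.default_rng(0)
    n, Q, K = 40, 4, 3
    G = np.hstack([np.ones((n, 1)), rng.normal(size=(n, Q))])
    w = rng.dirichlet(np.ones(K), size=n)
    pen = PenaltySpec(lambda1=1e5, lambda2=0.0)
    gamma = m_step_gamma(w, G, pen, max_iter=3000)
    assert np.all(gamma[:, 1:] == 0.0)
    # intercepts equal the log odds of the mean memberships vs class 1
    p = w.mean(axis=0)
    np.testing.assert_allclose(gamma[:, 0], np.log(p) - np.log(p[0]), atol=1e-4)


def test_gamma_unpenalized_matches_generic_optimizer():
    # overlapping classes so the unpenalized MLE is finite
    Q, K = 1, 2
    g = np.array([-1.0, -0.5, 0.2, 0.3, 1.0, 1.5])
    labels = np.array([0, 1, 0, 1, 0, 1])
    n = g.size
    G = np.column_stack([np.ones(n), g])
    w = np.zeros((n, K))
    w[np.arange(n), labels] = 1.0  # hard weights
    pen = PenaltySpec()
    gamma = m_step_gamma(w, G, pen, max_iter=5000, tol=1e-12)

    def negll(free):
        gm = np.vstack([np.zeros(Q + 1), free.reshape(K - 1, Q + 1)])
        pi = subtype_prior(gm, G)
        return -np.sum(w * np.log(np.maximum(pi, 1e-12)))

    res = minimize(negll, np.zeros((K - 1) * (Q + 1)), method="BFGS")
    gm_opt = np.vstack([np.zeros(Q + 1), res.x.reshape(K - 1, Q + 1)])
    np.testing.assert_allclose(
        subtype_prior(gamma, G), subtype_prior(gm_opt, G), atol=1e-5
    )


def test_gamma_group_penalty_kills_noise_pathway():
    """A pathway of pure noise features is zeroed out in most seeds."""
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        n, K = 80, 2
        G = np.hstack([np.ones((n, 1)), rng.normal(size=(n, 8))])
        # class determined by features 0..3 (pathway A); 4..7 are noise (pathway B)
        lp = 1.5 * G[:, 1:5].sum(axis=1)
        pclass = 1 / (1 + np.exp(-lp))
        w = np.zeros((n, K))
        w[:, 1] = rng.uniform(size=n) < pclass
        w[:, 0] = 1 - w[:, 1]
        pen = PenaltySpec(
            lambda1=0.5, lambda2=8.0, groups=[np.arange(0, 4), np.arange(4, 8)]
        )
        gamma = m_step_gamma(w, G, pen, max_iter=2000)
        if np.all(gamma[:, 5:9] == 0.0) and np.any(gamma[:, 1:5] != 0.0):
            hits += 1
    assert hits >= 9


# ---------------------------------------------------------------------------
# longitudinal M-step
# ---------------------------------------------------------------------------


def test_longitudinal_reduces_to_ols():
    study = make_tiny_study(n=8, seed=2)
    basis = build_basis(*study.time_range, nb=4)
    designs = assemble_designs(study, basis)
    d = designs.X.shape[1]
    c = m_step_longitudinal(designs, np.ones(study.n), np.zeros(study.n), np.zeros((d, d)))
    ols, *_ = np.linalg.lstsq(designs.X, designs.Y, rcond=None)
    np.testing.assert_allclose(c, ols, atol=1e-8)


def test_longitudinal_infinite_roughness_gives_affine():
    study = make_tiny_study(n=20, T_range=(4, 7), seed=3)
    basis = build_basis(*study.time_range, nb=6)
    designs = assemble_designs(study, basis)
    Q_mat = roughness_matrix(basis)
    nb = basis.nb
    P1 = study.static_covs.shape[1]
    U = np.zeros((designs.X.shape[1],) * 2)
    U[:nb, :nb] = 1e10 * Q_mat  # crush curvature of the intercept block
    c = m_step_longitudinal(designs, np.ones(study.n), np.zeros(study.n), U)
    theta0 = c[:nb]
    assert theta0 @ Q_mat @ theta0 < 1e-6  # affine null space reached


def test_longitudinal_matches_quadratic_oracle():
    """Closed-form solve equals the augmented least-squares minimizer of H2_k."""
    study = make_tiny_study(n=7, seed=4)
    basis = build_basis(*study.time_range, nb=4)
    designs = assemble_designs(study, basis)
    rng = np.random.default_rng(5)
    w_k = rng.uniform(0.1, 1.0, study.n)
    a_k = rng.normal(scale=0.3, size=study.n)
    Q_mat = roughness_matrix(basis)
    pen = PenaltySpec(nu=np.full(study.static_covs.shape[1], 0.7), kappa=np.full(study.M, 0.4))
    U = pen.build_U(Q_mat)
    got = m_step_longitudinal(designs, w_k, a_k, U)
    # oracle: minimize || sqrt(W)(y - a - Xc) ||^2 + c'Uc via augmented lstsq
    rows = designs.row_subject
    sw = np.sqrt(w_k[rows])
    L = np.linalg.cholesky(U + 1e-12 * np.eye(U.shape[0]))
    A = np.vstack([designs.X * sw[:, None], L.T])
    b = np.concatenate([(designs.Y - a_k[rows]) * sw, np.zeros(U.shape[0])])
    oracle, *_ = np.linalg.lstsq(A, b, rcond=None)
    np.testing.assert_allclose(got, oracle, atol=1e-8)


def test_variance_updates_literal_formula():
    study = make_tiny_study(n=5, seed=6)
    basis = build_basis(*study.time_range, nb=4)
    designs = assemble_designs(study, basis)
    rng = np.random.default_rng(7)
    w_k = rng.uniform(0.2, 1.0, study.n)
    a_k = rng.normal(size=study.n) * 0.2
    a2_k = a_k**2 + rng.uniform(0.01, 0.1, study.n)
    c = rng.normal(size=designs.X.shape[1])
    se, sa = m_step_variances(designs, w_k, a_k, a2_k, c)
    num_e = num_a = den = 0.0
    for i in range(study.n):
        Xi = designs.X[designs.row_subject == i]
        y = study.outcomes[i]
        for j in range(len(y)):
            r = y[j] - a_k[i] - Xi[j] @ c
            num_e += w_k[i] * (r**2 - a_k[i] ** 2 + a2_k[i])
            num_a += w_k[i] * a2_k[i]
            den += w_k[i]
    assert se == pytest.approx(np.sqrt(num_e / den), abs=1e-12)
    assert sa == pytest.approx(np.sqrt(num_a / den), abs=1e-12)


def test_variance_hard_weights_equal_mle():
    study = make_tiny_study(n=30, T_range=(3, 6), seed=8)
    basis = build_basis(*study.time_range, nb=4)
    designs = assemble_designs(study, basis)
    c = np.linalg.lstsq(designs.X, designs.Y, rcond=None)[0]
    se, sa = m_step_variances(
        designs, np.ones(study.n), np.zeros(study.n), np.zeros(study.n), c
    )
    resid = designs.Y - designs.X @ c
    assert se == pytest.approx(np.sqrt(np.mean(resid**2)), abs=1e-12)
    assert sa == 1e-6  # floored: no intercept mass


def test_variance_zero_residual_floor():
    study = make_tiny_study(n=4, seed=9)
    basis = build_basis(*study.time_range, nb=4)
    designs = assemble_designs(study, basis)
    # target exactly reproduced -> residuals zero -> floor kicks in
    c = np.linalg.lstsq(designs.X, designs.Y, rcond=None)[0]
    designs.Y = designs.X @ c
    se, sa = m_step_variances(designs, np.ones(study.n), np.zeros(study.n), np.zeros(study.n), c)
    assert se == 1e-6 and sa == 1e-6


# ---------------------------------------------------------------------------
# EM driver
# ---------------------------------------------------------------------------


def single_class_study(n=200, seed=0):
    """Data from a one-component model with known spline coefficients."""
    rng = np.random.default_rng(seed)
    basis = build_basis(0.0, 1.0, nb=5)
    theta = np.array([[1.0, 2.0, 0.5, -1.0, 0.3], [0.5, 0.5, 0.5, 0.5, 0.5]])
    xi = np.array([[0.2, -0.2, 0.4, 0.0, -0.3]])
    times, outcomes, covs = [], [], []
    x2 = rng.normal(size=n)
    for i in range(n):
        T = int(rng.integers(3, 7))
        t = np.sort(rng.uniform(0, 1, T))
        v = rng.normal(size=(T, 1))
        mean = (
            eval_curve(basis, theta[0], t)
            + x2[i] * eval_curve(basis, theta[1], t)
            + v[:, 0] * eval_curve(basis, xi[0], t)
        )
        y = mean + rng.normal() * 0.4 + rng.normal(size=T) * 0.3
        times.append(t)
        outcomes.append(y)
        covs.append(v)
    study = tp.LongStudy(
        subject_ids=np.array([f"S{i:04d}" for i in range(n)]),
        times=times,
        outcomes=outcomes,
        static_covs=np.column_stack([np.ones(n), x2]),
        long_covs=covs,
        omics=np.ones((n, 1)),
        feature_names=[],
    )
    return study, basis, theta, xi


def test_fit_em_k1_parameter_recovery():
    study, basis, theta, xi = single_class_study(n=200, seed=10)
    cfg = tp.FitConfig(K=1, spline_nb=5, nu=0.0, kappa=0.0, n_restarts=1, seed=0)
    fit = tp.fit_em(study, cfg, gamma_mode="intercept_only")
    t_grid = np.linspace(0.05, 0.95, 50)
    for p in range(2):
        err = eval_curve(fit.basis, fit.params.theta[0, p], t_grid) - eval_curve(
            basis, theta[p], t_grid
        )
        assert np.sqrt((err**2).mean()) < 0.15
    err = eval_curve(fit.basis, fit.params.xi[0, 0], t_grid) - eval_curve(basis, xi[0], t_grid)
    assert np.sqrt((err**2).mean()) < 0.15
    assert fit.params.sigma_eps[0] == pytest.approx(0.3, abs=0.06)
    assert fit.params.sigma_alpha[0] == pytest.approx(0.4, abs=0.08)


def test_em_trace_monotone(small_fit):
    trace = np.array(small_fit.trace)
    slack = 1e-8 * (1.0 + np.abs(trace[:-1]))
    assert np.all(np.diff(trace) >= -slack)


def test_em_weights_normalized(small_fit):
    np.testing.assert_allclose(small_fit.e_state.w.sum(axis=1), 1.0, atol=1e-10)


def test_fit_deterministic_and_order_invariant(scenario1):
    study, _ = tp.generate(scenario1, 80, 3)
    cfg = tp.FitConfig(
        K=2, lambda1=5.0, lambda2=5.0, nu=0.1, kappa=0.1, n_restarts=1, seed=0, tol=1e-10,
        max_iter=500,
    )
    fit_a = tp.fit_em(study, cfg)
    fit_b = tp.fit_em(study, cfg)
    np.testing.assert_array_equal(fit_a.params.theta, fit_b.params.theta)
    np.testing.assert_array_equal(fit_a.params.gamma, fit_b.params.gamma)
    # permuting subject order: same optimum (up to solver tolerance) after
    # label canonicalization
    perm = np.random.default_rng(4).permutation(study.n)
    fit_c = tp.fit_em(study.subset(perm), cfg)
    assert fit_c.trace[-1] == pytest.approx(fit_a.trace[-1], abs=1e-3)
    np.testing.assert_array_equal(
        np.sort(fit_a.selected_features), np.sort(fit_c.selected_features)
    )
    t_grid = np.linspace(*study.time_range, 50)
    np.testing.assert_allclose(
        fit_a.curves(t_grid)["beta"], fit_c.curves(t_grid)["beta"], atol=1e-2
    )


def test_canonical_order_descending_mean(small_fit):
    t_grid = np.linspace(*small_fit.basis.boundary, 64)
    means = [
        eval_curve(small_fit.basis, small_fit.params.theta[k, 0], t_grid).mean()
        for k in range(small_fit.params.K)
    ]
    assert means == sorted(means, reverse=True)
    np.testing.assert_array_equal(small_fit.params.gamma[0], 0.0)


def test_posterior_assign_matches_training_e_step(small_sim_study, small_fit):
    study, _ = small_sim_study
    post, labels = tp.posterior_assign(small_fit, study)
    np.testing.assert_allclose(post, small_fit.e_state.w, atol=1e-10)
    np.testing.assert_array_equal(labels, np.argmax(post, axis=1))


def test_posterior_assign_k1():
    study, *_ = single_class_study(n=30, seed=11)
    cfg = tp.FitConfig(K=1, spline_nb=5, n_restarts=1, seed=0)
    fit = tp.fit_em(study, cfg, gamma_mode="intercept_only")
    post, labels = tp.posterior_assign(fit, study)
    np.testing.assert_array_equal(labels, 0)
    np.testing.assert_allclose(post, 1.0)


def test_clinical_only_recovers_proportions():
    """Two-component outcome-only data: free mixture proportions recovered."""
    rng = np.random.default_rng(12)
    n = 240
    basis = build_basis(0.0, 1.0, nb=4)
    th = {0: np.array([2.0, 2.0, 2.0, 2.0]), 1: np.array([-1.0, -1.0, -1.0, -1.0])}
    times, outcomes, covs = [], [], []
    z = (rng.uniform(size=n) < 0.3).astype(int)  # 70/30 split
    for i in range(n):
        T = int(rng.integers(3, 6))
        t = np.sort(rng.uniform(0, 1, T))
        y = eval_curve(basis, th[z[i]], t) + rng.normal() * 0.3 + rng.normal(size=T) * 0.3
        times.append(t)
        outcomes.append(y)
        covs.append(np.zeros((T, 0)))
    study = tp.LongStudy(
        subject_ids=np.array([f"S{i:04d}" for i in range(n)]),
        times=times,
        outcomes=outcomes,
        static_covs=np.ones((n, 1)),
        long_covs=covs,
        omics=np.hstack([np.ones((n, 1)), rng.normal(size=(n, 2))]),
        feature_names=["f0", "f1"],
    )
    cfg = tp.FitConfig(K=2, spline_nb=4, nu=0.1, kappa=0.1, n_restarts=2, seed=0)
    fit = tp.fit_clinical_only(study, cfg)
    pi = subtype_prior(fit.params.gamma, study.omics)  # constant across subjects
    # canonical subtype 1 is the high-outcome (70%) component
    assert pi[0, 0] == pytest.approx(1 - z.mean(), abs=0.05)
    assert fit.selected_features.size == 0
    np.testing.assert_array_equal(fit.params.gamma[:, 1:], 0.0)


def test_clinical_only_equals_huge_lambda_limit(scenario1):
    study, _ = tp.generate(scenario1, 60, 5)
    cfg = tp.FitConfig(K=2, nu=0.1, kappa=0.1, n_restarts=1, seed=0)
    clin = tp.fit_clinical_only(study, cfg)
    shrunk = tp.fit_em(study, cfg.replace(lambda1=1e6))
    assert np.all(shrunk.params.gamma[:, 1:] == 0.0)
    t_grid = np.linspace(*study.time_range, 40)
    np.testing.assert_allclose(
        clin.curves(t_grid)["beta"], shrunk.curves(t_grid)["beta"], atol=5e-3
    )


def test_init_weights_shape():
    study = make_tiny_study(n=9, seed=13)
    w = _init_weights(study, 3, 0)
    assert w.shape == (9, 3)
    np.testing.assert_allclose(w.sum(axis=1), 1.0)
    assert w.max() == pytest.approx(0.9)
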