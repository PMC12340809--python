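"""Modified EM algorithm: penalized M-steps, restarts, label handling.

Each iteration alternates an exact E-step (posterior membership weights and
random-intercept moments, see :mod:`tpclust.model_core`) with three M-steps:

* ``m_step_gamma`` -- sparse-group-lasso-penalized, weighted multinomial
  logistic regression, solved by proximal gradient (FISTA) with the exact
  sparse-group-lasso proximal operator;
* ``m_step_longitudinal`` -- a closed-form weighted, roughness-penalized
  least-squares solve for the spline coefficients of each subtype;
* ``m_step_variances`` -- closed-form noise and random-intercept SD updates.

Convergence is declared on the relative change of the penalized observed-data
log-likelihood.  Multiple restarts (jittered K-means initializations) guard
against local optima, and fitted components are canonicalized by descending
time-averaged mean trajectory, so subtype 1 is always the highest-outcome
("resilient-like") component.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve
from sklearn.cluster import KMeans

from .data_io import FitConfig, LongStudy
from .model_core import (
    DesignMatrices,
    EStepState,
    ModelParams,
    PenaltySpec,
    assemble_designs,
    e_step,
    observed_loglik,
    subtype_prior,
)
from .splines import SplineBasis, build_basis, eval_curve, roughness_matrix

logger = logging.getLogger(__name__)

ZERO_THRESHOLD = 1e-8  # solver output below this is an exact zero
VAR_FLOOR = 1e-6  # lower bound on fitted SDs
EMPTY_W = 1e-4  # a component no subject reaches this weight is empty


class EmptyClusterError(RuntimeError):
    """A mixture component lost all posterior mass and could not be re-seeded."""


@dataclass
class FitResult:
    """Outcome of one EM fit.

    ``selected_features`` holds the 0-based indices of omics features with any
    nonzero logistic coefficient across subtypes; ``trace`` is the penalized
    observed log-likelihood per iteration.
    """

    params: ModelParams
    e_state: EStepState | None
    trace: list
    converged: bool
    n_iter: int
    seed: int | None
    selected_features: np.ndarray
    basis: SplineBasis
    config: object = None
    penalty: PenaltySpec | None = None
    effective_B: int | None = None

    def curves(self, t_grid: np.ndarray) -> dict:
        """Evaluate all fitted coefficient curves on a grid.

        Returns {"beta": (K, P+1, G), "rho": (K, M, G)}.
        """
        K, P1, _ = self.params.theta.shape
        M = self.params.xi.shape[1]
        G = len(t_grid)
        beta = np.empty((K, P1, G))
        rho = np.empty((K, M, G))
        for k in range(K):
            for p in range(P1):
                beta[k, p] = eval_curve(self.basis, self.params.theta[k, p], t_grid)
            for m in range(M):
                rho[k, m] = eval_curve(self.basis, self.params.xi[k, m], t_grid)
        return {"beta": beta, "rho": rho}


# ---------------------------------------------------------------------------
# M-steps
# ---------------------------------------------------------------------------


def _sgl_prox(Z: np.ndarray, step: float, penalty: PenaltySpec) -> np.ndarray:
    """Sparse-group-lasso proximal operator on the free gamma block.

    ``Z`` is (K-1, Q+1); column 0 (intercepts) is unpenalized.  Elementwise
    soft-thresholding by step*lambda1 is followed by blockwise group
    shrinkage by step*lambda2 over each pathway's columns (all subtypes).
    Exact for disjoint groups; overlapping groups are shrunk sequentially.
    """
    Z = Z.copy()
    if penalty.lambda1 > 0:
        t1 = step * penalty.lambda1
        Z[:, 1:] = np.sign(Z[:, 1:]) * np.maximum(np.abs(Z[:, 1:]) - t1, 0.0)
    if penalty.lambda2 > 0:
        t2 = step * penalty.lambda2
        for g in penalty.groups:
            block = Z[:, g + 1]
            nrm = np.linalg.norm(block)
            Z[:, g + 1] = 0.0 if nrm <= t2 else block * (1.0 - t2 / nrm)
    return Z


def _gamma_objective(
    Gm: np.ndarray, W: np.ndarray, gamma_free: np.ndarray, omega: np.ndarray
) -> tuple[float, np.ndarray]:
    """Smooth part of the (negated) H1 objective and its gradient.

    f(gamma) = sum_i omega_i [logsumexp_k g_i' gamma_k - sum_k w_ik g_i' gamma_k]
    with the reference subtype's predictor fixed at zero.
    """
    n = Gm.shape[0]
    lp = np.hstack([np.zeros((n, 1)), Gm @ gamma_free.T])  # (n, K)
    mx = lp.max(axis=1, keepdims=True)
    lse = mx[:, 0] + np.log(np.exp(lp - mx).sum(axis=1))
    f = float((omega * (lse - (W * lp).sum(axis=1))).sum())
    pi = np.exp(lp - lse[:, None])
    grad = ((omega[:, None] * (pi - W))[:, 1:]).T @ Gm  # (K-1, Q+1)
    return f, grad


def m_step_gamma(
    w: np.ndarray,
    omics_matrix: np.ndarray,
    penalty: PenaltySpec,
    gamma_init: np.ndarray | None = None,
    subject_weights: np.ndarray | None = None,
    max_iter: int = 1000,
    tol: float = 1e-9,
    lipschitz: float | None = None,
) -> np.ndarray:
    """Sparse-group-lasso-penalized weighted multinomial logistic M-step.

    Maximizes sum_i omega_i sum_k w_ik log pi_ik(gamma) - lambda1 ||gamma||_1
    - lambda2 sum_l ||gamma_{A_l}||_2 over gamma with row 1 fixed at zero and
    unpenalized intercepts, by FISTA with the exact SGL prox.  Entries below
    1e-8 in magnitude are returned as exact zeros.
    """
    n, Q1 = omics_matrix.shape
    K = w.shape[1]
    omega = np.ones(n) if subject_weights is None else np.asarray(subject_weights, float)
    if gamma_init is None:
        gamma_init = np.zeros((K, Q1))
    if K == 1:
        return np.zeros((1, Q1))
    X = gamma_init[1:].copy()
    if lipschitz is None:
        Gw = omics_matrix * np.sqrt(omega)[:, None]
        lipschitz = 0.5 * np.linalg.norm(Gw, 2) ** 2
    L = max(lipschitz, 1e-10)
    step = 1.0 / L
    Yv = X.copy()
    t_acc = 1.0
    f_prev = np.inf
    for it in range(max_iter):
        f_y, grad = _gamma_objective(omics_matrix, w, Yv, omega)
        X_new = _sgl_prox(Yv - step * grad, step, penalty)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_acc**2))
        Yv = X_new + ((t_acc - 1.0) / t_new) * (X_new - X)
        X, t_acc = X_new, t_new
        if (it + 1) % 10 == 0 or it == max_iter - 1:
            f_x, _ = _gamma_objective(omics_matrix, w, X, omega)
            gamma_full = np.vstack([np.zeros((1, Q1)), X])
            F = f_x + penalty.sparsity_value(gamma_full)
            if abs(f_prev - F) <= tol * (1.0 + abs(F)):
                break
            if F > f_prev + 1e-10 * (1.0 + abs(f_prev)):
                # monotone safeguard: shorten the step and restart momentum
                step *= 0.5
                Yv = X.copy()
                t_acc = 1.0
            f_prev = F
    gamma = np.vstack([np.zeros((1, Q1)), X])
    if penalty.lambda1 > 0 or penalty.lambda2 > 0:
        gamma[np.abs(gamma) < ZERO_THRESHOLD] = 0.0
    return gamma


def _gamma_intercept_only(w: np.ndarray, omega: np.ndarray, Q1: int) -> np.ndarray:
    """Closed-form intercept-only logistic M-step: free mixture proportions."""
    p = (omega[:, None] * w).sum(axis=0)
    p = np.maximum(p / p.sum(), 1e-12)
    gamma = np.zeros((w.shape[1], Q1))
    gamma[:, 0] = np.log(p) - np.log(p[0])
    return gamma


def m_step_longitudinal(
    designs: DesignMatrices,
    w_k: np.ndarray,
    a_k: np.ndarray,
    U_mat: np.ndarray,
    subject_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Closed-form weighted, roughness-penalized least squares for one subtype.

    Solves (X' W_k X + U) c = X' W_k (Y - alpha_k) where W_k expands the
    subject weights w_ik over each subject's rows and alpha_k stacks the
    E-step intercept moments a_ik.  A tiny ridge jitter is added on failure.
    """
    rows = designs.row_subject
    wr = w_k[rows]
    if subject_weights is not None:
        wr = wr * np.asarray(subject_weights, float)[rows]
    target = designs.Y - a_k[rows]
    Xw = designs.X * wr[:, None]
    A = designs.X.T @ Xw + U_mat
    b = Xw.T @ target
    for jitter in (0.0, 1e-8, 1e-6):
        try:
            return solve(A + jitter * np.eye(A.shape[0]), b, assume_a="pos")
        except np.linalg.LinAlgError:
            continue
    raise EmptyClusterError("singular longitudinal M-step system (empty subtype?)")


def m_step_variances(
    designs: DesignMatrices,
    w_k: np.ndarray,
    a_k: np.ndarray,
    a2_k: np.ndarray,
    coef_k: np.ndarray,
    subject_weights: np.ndarray | None = None,
) -> tuple[float, float]:
    """Closed-form SD updates for one subtype.

    sigma_eps^2 = sum_ij w_ik [(y - a_ik - x'c)^2 - a_ik^2 + a2_ik] / sum_ij w_ik
    sigma_alpha^2 = sum_ij w_ik a2_ik / sum_ij w_ik; both floored at 1e-6.
    """
    rows = designs.row_subject
    wr = w_k[rows]
    if subject_weights is not None:
        wr = wr * np.asarray(subject_weights, float)[rows]
    total = wr.sum()
    if total <= 0:
        raise EmptyClusterError("zero total weight in variance update")
    resid = designs.Y - a_k[rows] - designs.X @ coef_k
    corr = (a2_k - a_k * a_k)[rows]
    var_eps = float((wr * (resid * resid + corr)).sum() / total)
    var_alpha = float((wr * a2_k[rows]).sum() / total)
    return max(np.sqrt(max(var_eps, 0.0)), VAR_FLOOR), max(np.sqrt(max(var_alpha, 0.0)), VAR_FLOOR)


# ---------------------------------------------------------------------------
# EM driver
# ---------------------------------------------------------------------------


def _init_weights(study: LongStudy, K: int, seed: int) -> np.ndarray:
    """Initial memberships from K-means on per-subject (level, slope) summaries."""
    feats = np.zeros((study.n, 2))
    for i, (t, y) in enumerate(zip(study.times, study.outcomes)):
        if len(t) >= 2 and np.ptp(t) > 0:
            A = np.column_stack([np.ones_like(t), t])
            c, *_ = np.linalg.lstsq(A, y, rcond=None)
            feats[i] = c
        else:
            feats[i] = (y.mean(), 0.0)
    sd = feats.std(axis=0)
    feats = feats / np.where(sd > 0, sd, 1.0)
    if K == 1:
        return np.ones((study.n, 1))
    labels = KMeans(n_clusters=K, n_init=10, random_state=seed % (2**31)).fit_predict(feats)
    w = np.full((study.n, K), 0.1 / max(K - 1, 1))
    w[np.arange(study.n), labels] = 0.9
    return w / w.sum(axis=1, keepdims=True)


def _initial_params(
    study: LongStudy,
    designs: DesignMatrices,
    basis: SplineBasis,
    w: np.ndarray,
    penalty: PenaltySpec,
    gamma_mode: str,
    omega: np.ndarray,
    lipschitz: float | None,
) -> ModelParams:
    K = w.shape[1]
    nb = basis.nb
    P1 = study.static_covs.shape[1]
    M = study.M
    Q_mat = roughness_matrix(basis)
    U = penalty.build_U(Q_mat)
    zeros = np.zeros(study.n)
    theta = np.empty((K, P1, nb))
    xi = np.empty((K, M, nb))
    sig_e = np.empty(K)
    sig_a = np.empty(K)
    rows = designs.row_subject
    Tbar = designs.T.mean()
    for k in range(K):
        c = m_step_longitudinal(designs, w[:, k], zeros, U, omega)
        theta[k] = c[: P1 * nb].reshape(P1, nb)
        xi[k] = c[P1 * nb :].reshape(M, nb)
        resid = designs.Y - designs.X @ c
        wr = (w[:, k] * omega)[rows]
        tot = max(wr.sum(), 1e-12)
        var = float((wr * resid * resid).sum() / tot)
        # split total residual variance: subject-mean spread seeds sigma_alpha
        S = np.add.reduceat(resid, designs.offsets)
        m_i = S / designs.T
        wi = w[:, k] * omega
        var_between = float((wi * m_i * m_i).sum() / max(wi.sum(), 1e-12))
        sa2 = max(var_between - var / Tbar, 0.05 * var)
        sig_a[k] = np.sqrt(max(sa2, VAR_FLOOR**2))
        sig_e[k] = np.sqrt(max(var - sa2, 0.25 * var))
    if gamma_mode == "intercept_only":
        gamma = _gamma_intercept_only(w, omega, study.omics.shape[1])
    else:
        gamma = m_step_gamma(
            w, study.omics, penalty, None, omega, max_iter=300, lipschitz=lipschitz
        )
    return ModelParams(gamma=gamma, theta=theta, xi=xi, sigma_eps=sig_e, sigma_alpha=sig_a)


def _penalized_observed(
    params: ModelParams,
    study: LongStudy,
    designs: DesignMatrices,
    penalty: PenaltySpec,
    Q_mat: np.ndarray,
    omega: np.ndarray | None,
) -> float:
    return (
        observed_loglik(params, study, designs, subject_weights=omega)
        - penalty.sparsity_value(params.gamma)
        - penalty.roughness_value(params, Q_mat)
    )


def _em_once(
    study: LongStudy,
    designs: DesignMatrices,
    basis: SplineBasis,
    config: FitConfig,
    penalty: PenaltySpec,
    w_init: np.ndarray | None = None,
    params: ModelParams | None = None,
    gamma_mode: str = "penalized",
    subject_weights: np.ndarray | None = None,
) -> tuple[ModelParams, EStepState, list, bool, int]:
    """One EM run from a given initialization; returns the raw (unrelabeled) fit."""
    K = config.K
    omega = np.ones(study.n) if subject_weights is None else np.asarray(subject_weights, float)
    Q_mat = roughness_matrix(basis)
    U = penalty.build_U(Q_mat)
    P1 = study.static_covs.shape[1]
    nb = basis.nb
    Gw = study.omics * np.sqrt(omega)[:, None]
    lipschitz = 0.5 * np.linalg.norm(Gw, 2) ** 2 if gamma_mode == "penalized" or gamma_mode == "free" else None
    if params is None:
        params = _initial_params(
            study, designs, basis, w_init, penalty, gamma_mode, omega, lipschitz
        )
    trace: list = []
    converged = False
    reseeds = np.zeros(K, dtype=int)
    state = None
    it = 0
    for it in range(1, config.max_iter + 1):
        state = e_step(params, study, designs)
        # empty-component guard: re-seed from the worst-fit subjects
        empty = np.flatnonzero(state.w.max(axis=0) < EMPTY_W)
        for k in empty:
            reseeds[k] += 1
            if reseeds[k] > 2:
                raise EmptyClusterError(f"component {k} repeatedly empty")
            logger.warning("re-seeding empty component %d", k)
            # seed from the most ambiguous subjects (lowest max posterior)
            order = np.argsort(state.w.max(axis=1))
            worst = order[: max(2, study.n // (5 * K))]
            state.w[worst] = 0.1 / max(K - 1, 1)
            state.w[worst, k] = 0.9
            state.w /= state.w.sum(axis=1, keepdims=True)
        # M-steps
        if gamma_mode == "intercept_only":
            gamma = _gamma_intercept_only(state.w, omega, study.omics.shape[1])
        else:
            gamma = m_step_gamma(
                state.w, study.omics, penalty, params.gamma, omega,
                max_iter=500, lipschitz=lipschitz,
            )
        theta = np.empty_like(params.theta)
        xi = np.empty_like(params.xi)
        sig_e = np.empty(K)
        sig_a = np.empty(K)
        for k in range(K):
            c = m_step_longitudinal(designs, state.w[:, k], state.a[:, k], U, omega)
            theta[k] = c[: P1 * nb].reshape(P1, nb)
            xi[k] = c[P1 * nb :].reshape(-1, nb)
            sig_e[k], sig_a[k] = m_step_variances(
                designs, state.w[:, k], state.a[:, k], state.a2[:, k], c, omega
            )
        params = ModelParams(gamma=gamma, theta=theta, xi=xi, sigma_eps=sig_e, sigma_alpha=sig_a)
        obj = _penalized_observed(params, study, designs, penalty, Q_mat, subject_weights)
        trace.append(obj)
        if len(trace) >= 2:
            if abs(trace[-1] - trace[-2]) <= config.tol * (1.0 + abs(trace[-2])):
                converged = True
                break
    state = e_step(params, study, designs)
    return params, state, trace, converged, it


def _canonicalize(params: ModelParams, state: EStepState, basis: SplineBasis) -> tuple:
    """Relabel components by descending time-averaged mean trajectory mu_k."""
    grid = np.linspace(*basis.boundary, 64)
    means = np.array([eval_curve(basis, params.theta[k, 0], grid).mean() for k in range(params.K)])
    order = np.argsort(-means, kind="stable")
    gamma = params.gamma[order]
    gamma = gamma - gamma[0]  # restore the gamma_1 = 0 gauge
    new = ModelParams(
        gamma=gamma,
        theta=params.theta[order],
        xi=params.xi[order],
        sigma_eps=params.sigma_eps[order],
        sigma_alpha=params.sigma_alpha[order],
    )
    new_state = EStepState(
        w=state.w[:, order], a=state.a[:, order], a2=state.a2[:, order], loglik=state.loglik
    )
    return new, new_state


def _penalty_from_config(config: FitConfig, study: LongStudy) -> PenaltySpec:
    P1 = study.static_covs.shape[1]
    return PenaltySpec(
        lambda1=config.lambda1,
        lambda2=config.lambda2,
        groups=list(study.pathway_groups.values()),
        nu=np.full(P1, config.nu),
        kappa=np.full(study.M, config.kappa),
    )


def fit_em(
    study: LongStudy,
    config: FitConfig,
    penalty: PenaltySpec | None = None,
    gamma_mode: str = "penalized",
    subject_weights: np.ndarray | None = None,
    params_init: ModelParams | None = None,
) -> FitResult:
    """Fit the mixture by the modified EM algorithm with restarts.

    The best of ``config.n_restarts`` runs (by final penalized observed
    log-likelihood) is returned, with components canonicalized by descending
    time-averaged mean curve.  ``params_init`` bypasses the K-means restarts
    entirely (single warm-started run; used by the multiplier bootstrap).
    """
    if penalty is None:
        penalty = _penalty_from_config(config, study)
    basis = build_basis(
        *study.time_range,
        nb=config.spline_nb,
        degree=config.spline_degree,
        knot_rule=config.knot_rule,
        times=np.concatenate(study.times),
    )
    designs = assemble_designs(study, basis)
    seed = 0 if config.seed is None else int(config.seed)
    best = None
    if params_init is not None:
        out = _em_once(
            study, designs, basis, config, penalty,
            params=params_init.copy(), gamma_mode=gamma_mode,
            subject_weights=subject_weights,
        )
        best = out
    else:
        n_fail = 0
        for r in range(max(config.n_restarts, 1)):
            try:
                w0 = _init_weights(study, config.K, seed + 7919 * r)
                out = _em_once(
                    study, designs, basis, config, penalty,
                    w_init=w0, gamma_mode=gamma_mode, subject_weights=subject_weights,
                )
            except EmptyClusterError as exc:
                logger.warning("restart %d failed: %s", r, exc)
                n_fail += 1
                continue
            if best is None or out[2][-1] > best[2][-1]:
                best = out
        if best is None:
            if config.K > 1:
                warnings.warn(
                    f"all restarts collapsed a component; refitting with K={config.K - 1}",
                    RuntimeWarning,
                )
                return fit_em(
                    study, config.replace(K=config.K - 1), None if penalty is None else penalty,
                    gamma_mode=gamma_mode, subject_weights=subject_weights,
                )
            raise EmptyClusterError("EM failed for K=1")
    params, state, trace, converged, n_iter = best
    params, state = _canonicalize(params, state, basis)
    selected = np.flatnonzero(np.any(params.gamma[:, 1:] != 0.0, axis=0))
    return FitResult(
        params=params,
        e_state=state,
        trace=trace,
        converged=converged,
        n_iter=n_iter,
        seed=config.seed,
        selected_features=selected,
        basis=basis,
        config=config,
        penalty=penalty,
    )


def fit_clinical_only(study: LongStudy, config: FitConfig) -> FitResult:
    """Outcome-trajectory-only variant: free mixture proportions, no omics.

    The membership prior reduces to an intercept-only logistic model and all
    sparsity penalties are dropped; the longitudinal sub-model, roughness
    penalties and EM machinery are unchanged.
    """
    cfg = config.replace(lambda1=0.0, lambda2=0.0)
    penalty = PenaltySpec(
        lambda1=0.0,
        lambda2=0.0,
        groups=[],
        nu=np.full(study.static_covs.shape[1], cfg.nu),
        kappa=np.full(study.M, cfg.kappa),
    )
    fit = fit_em(study, cfg, penalty, gamma_mode="intercept_only")
    fit.selected_features = np.array([], dtype=int)
    return fit


def posterior_assign(fit: FitResult, study: LongStudy) -> tuple[np.ndarray, np.ndarray]:
    """Posterior membership probabilities and hard labels for any study.

    posterior_ik = pi_ik f_k(y_i) / sum_r pi_ir f_r(y_i); the hard label is
    the argmax with ties broken by the lowest subtype index.
    """
    designs = assemble_designs(study, fit.basis)
    state = e_step(fit.params, study, designs)
    labels = np.argmax(state.w, axis=1)
    return state.w, labels
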