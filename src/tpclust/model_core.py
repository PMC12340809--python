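"""Probability model for outcome-guided subtyping with time-varying effects.

The model is a finite mixture over K latent subtypes.  Membership priors are
multinomial-logistic in the omics vector g_i (coefficients gamma_k, with
gamma_1 = 0 for identifiability).  Conditional on subtype k, the outcome
trajectory follows

    y_i(t_ij) = alpha_ik + sum_p x_ip beta_pk(t_ij)
                + sum_m v_im(t_ij) rho_mk(t_ij) + eps_ijk,

with a Gaussian random intercept alpha_ik ~ N(0, sigma_alpha_k^2) and noise
eps ~ N(0, sigma_eps_k^2).  Each smooth effect is expanded in a shared
B-spline basis, so the within-subtype mean is linear in the stacked spline
coefficients (theta_k, xi_k), and the within-subject covariance is compound
symmetric: sigma_eps^2 I + sigma_alpha^2 11'.  All mixture arithmetic is done
in log space; the rank-one covariance is handled with Sherman-Morrison, so the
per-subject likelihood costs O(T_i) rather than O(T_i^3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .data_io import LongStudy
from .splines import SplineBasis, eval_basis, roughness_matrix

LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class ModelParams:
    """Full parameter vector eta = {gamma, theta, xi, sigma_eps, sigma_alpha}.

    gamma : (K, Q+1) logistic coefficients, column 0 = intercept, row 0 fixed
        to zero (reference subtype).
    theta : (K, P+1, nb) spline coefficients of the static-covariate effects;
        theta[:, 0] parameterizes the subtype mean trajectory mu_k(t).
    xi : (K, M, nb) spline coefficients of the longitudinal-covariate effects.
    sigma_eps, sigma_alpha : (K,) noise and random-intercept SDs.
    """

    gamma: np.ndarray
    theta: np.ndarray
    xi: np.ndarray
    sigma_eps: np.ndarray
    sigma_alpha: np.ndarray

    def __post_init__(self) -> None:
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        self.theta = np.asarray(self.theta, dtype=float)
        self.xi = np.asarray(self.xi, dtype=float)
        self.sigma_eps = np.atleast_1d(np.asarray(self.sigma_eps, dtype=float))
        self.sigma_alpha = np.atleast_1d(np.asarray(self.sigma_alpha, dtype=float))
        self.validate()

    def validate(self) -> None:
        if not np.allclose(self.gamma[0], 0.0):
            raise ValueError("gamma row for the reference subtype must be zero")
        if np.any(self.sigma_eps <= 0):
            raise ValueError("sigma_eps must be strictly positive")
        if np.any(self.sigma_alpha < 0):
            raise ValueError("sigma_alpha must be nonnegative")
        for arr in (self.gamma, self.theta, self.xi, self.sigma_eps, self.sigma_alpha):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite model parameters")

    @property
    def K(self) -> int:
        return self.gamma.shape[0]

    @property
    def nb(self) -> int:
        return self.theta.shape[2]

    def coef_matrix(self) -> np.ndarray:
        """Stacked spline coefficients, shape ((P+1+M)*nb, K).

        Column order matches the design matrix: static-covariate blocks
        p = 0..P first, then longitudinal blocks m = 1..M.
        """
        K = self.K
        flat = [
            np.concatenate([self.theta[k].ravel(), self.xi[k].ravel()]) for k in range(K)
        ]
        return np.column_stack(flat)

    def copy(self) -> "ModelParams":
        return ModelParams(
            gamma=self.gamma.copy(),
            theta=self.theta.copy(),
            xi=self.xi.copy(),
            sigma_eps=self.sigma_eps.copy(),
            sigma_alpha=self.sigma_alpha.copy(),
        )


@dataclass
class PenaltySpec:
    """Sparsity and roughness penalty configuration.

    lambda1 : elementwise L1 weight on the non-intercept gamma entries.
    lambda2 : group-L2 weight; each group is the block of gamma entries (all
        subtypes) for the features in one pathway index set A_l.
    groups : list of integer arrays of 0-based feature indices (0..Q-1).
    nu : (P+1,) roughness weights for the beta_pk curves (shared across k).
    kappa : (M,) roughness weights for the rho_mk curves (shared across k).
    """

    lambda1: float = 0.0
    lambda2: float = 0.0
    groups: list = field(default_factory=list)
    nu: np.ndarray = field(default_factory=lambda: np.zeros(1))
    kappa: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.nu = np.atleast_1d(np.asarray(self.nu, dtype=float))
        self.kappa = np.atleast_1d(np.asarray(self.kappa, dtype=float))
        if self.lambda1 < 0 or self.lambda2 < 0 or np.any(self.nu < 0) or np.any(self.kappa < 0):
            raise ValueError("penalty weights must be nonnegative")
        self.groups = [np.asarray(g, dtype=int) for g in self.groups]

    def build_U(self, Q_mat: np.ndarray) -> np.ndarray:
        """Block-diagonal roughness matrix U matching the design columns."""
        nb = Q_mat.shape[0]
        weights = np.concatenate([self.nu, self.kappa])
        d = weights.size * nb
        U = np.zeros((d, d))
        for b, wgt in enumerate(weights):
            sl = slice(b * nb, (b + 1) * nb)
            U[sl, sl] = wgt * Q_mat
        return U

    def sparsity_value(self, gamma: np.ndarray) -> float:
        """lambda1 * sum |gamma_kq| + lambda2 * sum_l ||gamma_{A_l}||_2.

        Intercepts (column 0) are never penalized; q runs over 1..Q.
        """
        val = self.lambda1 * np.abs(gamma[:, 1:]).sum()
        for g in self.groups:
            val += self.lambda2 * np.linalg.norm(gamma[:, g + 1])
        return float(val)

    def roughness_value(self, params: ModelParams, Q_mat: np.ndarray) -> float:
        """sum_p nu_p sum_k R(theta_pk) + sum_m kappa_m sum_k R(xi_mk)."""
        val = 0.0
        for p, nu_p in enumerate(self.nu):
            th = params.theta[:, p, :]
            val += nu_p * float(np.einsum("kr,rs,ks->", th, Q_mat, th))
        for m, ka_m in enumerate(self.kappa):
            xi = params.xi[:, m, :]
            val += ka_m * float(np.einsum("kr,rs,ks->", xi, Q_mat, xi))
        return val


@dataclass
class EStepState:
    """Posterior moments from one E-step.

    w : (n, K) posterior membership weights, rows sum to one.
    a : (n, K) conditional means of the random intercept given membership
        (the compound-symmetry BLUP).
    a2 : (n, K) conditional second moments of the random intercept given
        membership (a^2 plus the conditional variance).
    loglik : observed-data log-likelihood at the parameters used.
    """

    w: np.ndarray
    a: np.ndarray
    a2: np.ndarray
    loglik: float = np.nan


@dataclass
class DesignMatrices:
    """Stacked longitudinal design over all (i, j) rows.

    Y : (N,) outcomes; X : (N, (P+1+M)*nb) spline-expanded covariates;
    row_subject : (N,) subject index per row; T : (n,) visits per subject;
    offsets : (n,) start row of each subject's contiguous block.
    """

    Y: np.ndarray
    X: np.ndarray
    row_subject: np.ndarray
    T: np.ndarray
    offsets: np.ndarray


def assemble_designs(study: LongStudy, basis: SplineBasis) -> DesignMatrices:
    """Build the stacked design: blocks x_ip * b(t_ij)' then v_im(t_ij) * b(t_ij)'."""
    nb = basis.nb
    P1 = study.static_covs.shape[1]  # P + 1 including intercept
    M = study.M
    Y = np.concatenate(study.outcomes)
    T = np.array([len(t) for t in study.times])
    row_subject = np.repeat(np.arange(study.n), T)
    t_all = np.concatenate(study.times)
    B = eval_basis(basis, t_all)  # (N, nb)
    cols = []
    Xstat = study.static_covs[row_subject]  # (N, P+1)
    for p in range(P1):
        cols.append(Xstat[:, p : p + 1] * B)
    if M:
        V = np.vstack(study.long_covs)  # (N, M)
        for m in range(M):
            cols.append(V[:, m : m + 1] * B)
    X = np.hstack(cols)
    offsets = np.concatenate([[0], np.cumsum(T)[:-1]])
    return DesignMatrices(Y=Y, X=X, row_subject=row_subject, T=T, offsets=offsets)


# ---------------------------------------------------------------------------
# likelihood pieces
# ---------------------------------------------------------------------------


def subtype_prior(gamma: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Softmax membership priors pi_ik = exp(g' gamma_k) / sum_r exp(g' gamma_r).

    ``g`` may be a single (Q+1,) vector or an (n, Q+1) matrix; a leading
    intercept entry of 1 is expected.  Computed max-shifted for overflow
    safety.
    """
    lp = np.atleast_2d(g) @ gamma.T  # (n, K)
    if not np.all(np.isfinite(lp)):
        raise ValueError("non-finite linear predictor in subtype prior")
    lp = lp - lp.max(axis=1, keepdims=True)
    e = np.exp(lp)
    pi = e / e.sum(axis=1, keepdims=True)
    return pi[0] if np.asarray(g).ndim == 1 else pi


def _suff_stats(designs: DesignMatrices, coef: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject residual sums: (n, K) of sum_j r_ij and sum_j r_ij^2."""
    resid = designs.Y[:, None] - designs.X @ coef  # (N, K)
    S = np.add.reduceat(resid, designs.offsets, axis=0)
    rss = np.add.reduceat(resid * resid, designs.offsets, axis=0)
    return S, rss


def _component_logliks(
    designs: DesignMatrices, params: ModelParams
) -> tuple[np.ndarray, np.ndarray]:
    """log f_{y,k}(y_i) for every subject and subtype via Sherman-Morrison.

    Returns (logf, S) with logf (n, K) marginal Gaussian log-densities and S
    (n, K) per-subject residual sums (reused by the E-step moments).
    """
    S, rss = _suff_stats(designs, params.coef_matrix())
    T = designs.T[:, None].astype(float)  # (n, 1)
    d = params.sigma_eps[None, :] ** 2  # (1, K)
    s2 = params.sigma_alpha[None, :] ** 2
    denom = d + T * s2  # (n, K)
    quad = (rss - (s2 / denom) * S * S) / d
    logdet = T * np.log(d) + np.log1p(T * s2 / d)
    logf = -0.5 * (T * LOG_2PI + logdet + quad)
    return logf, S


def marginal_loglik_subject(
    y: np.ndarray,
    X_rows: np.ndarray,
    coef_k: np.ndarray,
    sigma_eps: float,
    sigma_alpha: float,
) -> float:
    """Gaussian log-density of one subject's trajectory under one subtype.

    Mean X_i c_k, covariance sigma_eps^2 I + sigma_alpha^2 11' evaluated with
    the Sherman-Morrison identity in O(T_i).
    """
    if sigma_eps <= 0:
        raise ValueError("sigma_eps must be positive")
    y = np.asarray(y, dtype=float)
    r = y - np.asarray(X_rows) @ np.asarray(coef_k)
    T = y.size
    d = sigma_eps**2
    s2 = sigma_alpha**2
    Ssum = r.sum()
    quad = (r @ r - (s2 / (d + T * s2)) * Ssum**2) / d
    logdet = T * np.log(d) + np.log1p(T * s2 / d)
    return float(-0.5 * (T * LOG_2PI + logdet + quad))


def observed_loglik(
    params: ModelParams,
    study: LongStudy,
    designs: DesignMatrices | None = None,
    subject_weights: np.ndarray | None = None,
) -> float:
    """Observed-data log-likelihood sum_i log sum_k pi_ik f_{y,k}(y_i).

    ``subject_weights`` (optional, nonnegative) multiply each subject's
    contribution; used by the multiplier bootstrap.
    """
    from .splines import build_basis  # local import to avoid cycles at module load

    if designs is None:
        basis = build_basis(*study.time_range, nb=params.nb)
        designs = assemble_designs(study, basis)
    logf, _ = _component_logliks(designs, params)
    logpi = np.log(np.maximum(subtype_prior(params.gamma, study.omics), 1e-300))
    per_subject = logsumexp(logpi + logf, axis=1)
    if subject_weights is not None:
        per_subject = per_subject * subject_weights
    return float(per_subject.sum())


def e_step(
    params: ModelParams, study: LongStudy, designs: DesignMatrices
) -> EStepState:
    """Posterior membership weights and random-intercept moments.

    w_ik = pi_ik f_k(y_i) / sum_r pi_ir f_r(y_i), computed in log space.
    a_ik = E[alpha_ik | y_i, z_ik = 1] = sigma_alpha^2 1' Sigma_k^{-1}
    (y_i - mean_ik), reduced by Sherman-Morrison to sigma_alpha^2 S_ik /
    (sigma_eps^2 + T_i sigma_alpha^2) with S_ik the residual sum (the
    random-intercept BLUP); a2_ik = E[alpha_ik^2 | y_i, z_ik = 1] = a_ik^2 +
    sigma_alpha^2 - sigma_alpha^4 T_i / (sigma_eps^2 + T_i sigma_alpha^2).
    The membership weight enters the M-steps through W_k, so the intercept
    moments are the exact conditional moments given membership.
    """
    logf, S = _component_logliks(designs, params)
    logpi = np.log(np.maximum(subtype_prior(params.gamma, study.omics), 1e-300))
    joint = logpi + logf
    norm = logsumexp(joint, axis=1, keepdims=True)
    w = np.exp(joint - norm)
    T = designs.T[:, None].astype(float)
    d = params.sigma_eps[None, :] ** 2
    s2 = params.sigma_alpha[None, :] ** 2
    denom = d + T * s2
    a = s2 * S / denom
    a2 = a * a + (s2 - s2 * s2 * T / denom)
    return EStepState(w=w, a=a, a2=a2, loglik=float(norm.sum()))


def penalized_objective(
    params: ModelParams,
    e_state: EStepState,
    study: LongStudy,
    penalty: PenaltySpec,
    designs: DesignMatrices | None = None,
    basis: SplineBasis | None = None,
    subject_weights: np.ndarray | None = None,
) -> float:
    """EM surrogate H(eta | eta^(s)) = H1(gamma) + sum_k H2_k(theta_k, xi_k).

    H1 is the w-weighted multinomial log-likelihood minus the sparse-group
    penalties; H2_k is the negative weighted sum of squares around the
    spline mean (with the a2 - a^2 correction term carried, and the Gaussian
    normalizing constants dropped) minus the roughness penalties.
    """
    if basis is None:
        basis = SplineBasis(degree=3, interior_knots=np.linspace(*study.time_range, params.nb - 2)[1:-1], boundary=study.time_range)
    if designs is None:
        designs = assemble_designs(study, basis)
    w, a, a2 = e_state.w, e_state.a, e_state.a2
    omega = np.ones(study.n) if subject_weights is None else np.asarray(subject_weights, float)
    logpi = np.log(np.maximum(subtype_prior(params.gamma, study.omics), 1e-300))
    H1 = float(((omega[:, None] * w) * logpi).sum()) - penalty.sparsity_value(params.gamma)
    rows = designs.row_subject
    resid = designs.Y[:, None] - a[rows] - designs.X @ params.coef_matrix()  # (N, K)
    per_row = resid * resid + (a2 - a * a)[rows]
    H2_data = -float(((omega[:, None] * w)[rows] * per_row).sum())
    Q_mat = roughness_matrix(basis)
    return H1 + H2_data - penalty.roughness_value(params, Q_mat)
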