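"""Relaxed-lasso + K-fold cross-validation tuning of penalties and K.

For a candidate tuning point, the sparsity-penalized model is fitted once on
the full data to obtain the selected feature set S.  Cross-validation then
scores S with the shrinkage bias removed: within each fold the model is
refitted on the training subjects using only the features in S and *no*
sparsity penalties (roughness penalties retained; coefficients outside S
pinned at zero), and the observed-data negative log-likelihood of the
held-out subjects is the validation loss.  The tuning point -- including the
subtype count K -- minimizing the summed held-out loss wins.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from .data_io import FitConfig, LongStudy
from .em_fit import FitResult, _init_weights, fit_clinical_only, fit_em
from .model_core import PenaltySpec, observed_loglik

logger = logging.getLogger(__name__)


def relaxed_refit(
    study: LongStudy, S: np.ndarray, config: FitConfig
) -> FitResult:
    """Refit with omics restricted to S and all sparsity penalties removed.

    Roughness penalties are retained.  The returned gamma is re-embedded at
    full width with the non-selected entries fixed at zero.  An empty S
    reduces to the outcome-only model with free mixture proportions.
    """
    S = np.asarray(S, dtype=int)
    cfg = config.replace(lambda1=0.0, lambda2=0.0)
    if S.size == 0:
        fit = fit_clinical_only(study, cfg)
        Q1 = study.omics.shape[1]
        gamma_full = np.zeros((fit.params.K, Q1))
        gamma_full[:, 0] = fit.params.gamma[:, 0]
        fit.params.gamma = gamma_full
        return fit
    sub = study.restrict_features(S)
    penalty = PenaltySpec(
        lambda1=0.0, lambda2=0.0, groups=[],
        nu=np.full(study.static_covs.shape[1], cfg.nu),
        kappa=np.full(study.M, cfg.kappa),
    )
    fit = fit_em(sub, cfg, penalty, gamma_mode="free")
    gamma_full = np.zeros((fit.params.K, study.omics.shape[1]))
    gamma_full[:, 0] = fit.params.gamma[:, 0]
    gamma_full[:, S + 1] = fit.params.gamma[:, 1:]
    fit.params.gamma = gamma_full
    fit.selected_features = S
    return fit


def _fold_assignment(n: int, folds: int, K: int, rng: np.random.Generator) -> np.ndarray:
    """Seed-reproducible subject-level folds; folds smaller than K are merged."""
    folds = max(2, min(folds, n // max(K, 1)))
    assign = np.repeat(np.arange(folds), int(np.ceil(n / folds)))[:n]
    rng.shuffle(assign)
    return assign


def cv_loss(
    study: LongStudy, config: FitConfig, folds: int = 5, seed: int = 0
) -> tuple[float, np.ndarray]:
    """Cross-validated held-out negative log-likelihood at one tuning point.

    Selection runs once on the full data; each fold then gets a relaxed refit
    on its training subjects and is scored by the held-out observed negative
    log-likelihood.  Returns (total held-out NLL, selected set S).
    """
    full = fit_em(study, config)
    S = full.selected_features
    rng = np.random.default_rng(seed)
    assign = _fold_assignment(study.n, folds, config.K, rng)
    total = 0.0
    from .model_core import assemble_designs

    for f in np.unique(assign):
        train = study.subset(np.flatnonzero(assign != f))
        test = study.subset(np.flatnonzero(assign == f))
        refit = relaxed_refit(train, S, config)
        # score on the training fit's basis (test times clamp to its range)
        test_designs = assemble_designs(test, refit.basis)
        total -= observed_loglik(refit.params, test, test_designs)
    return float(total), S


def tune(
    study: LongStudy,
    grids: dict,
    folds: int = 5,
    seed: int = 0,
    config_base: FitConfig | None = None,
) -> tuple[FitConfig, pd.DataFrame]:
    """Full-factorial grid search over tuning parameters (and optionally K).

    ``grids`` maps FitConfig field names (lambda1, lambda2, nu, kappa, K) to
    candidate value lists.  Returns the winning configuration and the full CV
    table for audit.
    """
    base = config_base or FitConfig()
    keys = list(grids)
    rows = []
    best_cfg, best_loss = None, np.inf
    for combo in itertools.product(*(grids[k] for k in keys)):
        cfg = base.replace(**dict(zip(keys, combo)))
        loss, S = cv_loss(study, cfg, folds=folds, seed=seed)
        rows.append({**dict(zip(keys, combo)), "cv_loss": loss, "n_selected": len(S)})
        logger.info("tuning point %s -> loss %.3f (|S|=%d)", dict(zip(keys, combo)), loss, len(S))
        if loss < best_loss:
            best_cfg, best_loss = cfg, loss
    return best_cfg, pd.DataFrame(rows)


def suggest_penalty_grid(
    study: LongStudy, config: FitConfig, fractions=(0.3, 0.1, 0.03), seed: int = 0
) -> dict:
    """Scale-aware lambda grids as fractions of the data-driven maxima.

    lambda1_max is the largest absolute score-equation entry at gamma = 0
    (evaluated at the K-means initial memberships); lambda2_max the largest
    pathway-block norm of the same score.  Fractions of these maxima span the
    useful range without hand calibration.
    """
    w0 = _init_weights(study, config.K, seed)
    G = study.omics
    score = ((1.0 / config.K) - w0)[:, 1:].T @ G  # (K-1, Q+1), gamma = 0 gradient
    lam1_max = float(np.abs(score[:, 1:]).max())
    lam2_max = 0.0
    for g in study.pathway_groups.values():
        lam2_max = max(lam2_max, float(np.linalg.norm(score[:, np.asarray(g) + 1])))
    lam2_max = lam2_max or lam1_max
    return {
        "lambda1": [round(f * lam1_max, 6) for f in fractions],
        "lambda2": [round(f * lam2_max, 6) for f in fractions],
    }
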