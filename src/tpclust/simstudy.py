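"""Reusable simulation-study workflows: tuning, coverage, IMSE and selection.

These functions reproduce the evaluation pipeline used to validate the
method: generate replicate datasets from a scenario preset, tune penalties by
relaxed-lasso cross-validation on the first replicate, fit every replicate at
the tuned point, and score estimation (IMSE), inference (pointwise coverage
of the multiplier-bootstrap bands) and feature selection (FDR/TDR) against
the generating truths.  Problem sizes are arguments so studies scale from
smoke tests to paper-scale runs.
"""

from __future__ import annotations

import logging

import numpy as np

from .bootstrap import bootstrap_bands
from .data_io import FitConfig
from .em_fit import fit_em
from .evaluate import empirical_coverage, fdr_tdr, imse, match_components
from .simulate import SimConfig, generate, scenario_preset, truth_curves
from .tuning import suggest_penalty_grid, tune

logger = logging.getLogger(__name__)

N_GRID = 100  # evaluation grid size on [0, 1]


def tune_on_replicate(
    sim: SimConfig,
    n: int,
    seed: int,
    base: FitConfig | None = None,
    folds: int = 3,
    nu_grid=(1.0, 0.1, 0.01),
) -> FitConfig:
    """Two-stage tuning on one replicate: sparsity first, then smoothness.

    Stage 1 searches the scale-aware lambda grids (fractions of the
    data-driven maxima) at the base smoothness; stage 2 refines a shared
    nu = kappa over ``nu_grid`` at the winning lambdas.  The tuned point is
    reused across replicates of a study.
    """
    base = base or FitConfig(K=3, n_restarts=2)
    study, _ = generate(sim, n, seed)
    grids = suggest_penalty_grid(study, base, seed=seed)
    best, _ = tune(study, grids, folds=folds, seed=seed, config_base=base)
    best, _ = tune(
        study,
        {"nu": list(nu_grid), "kappa": list(nu_grid)},
        folds=folds,
        seed=seed,
        config_base=best,
    )
    logger.info(
        "tuned: lambda1=%.3g lambda2=%.3g nu=%.3g kappa=%.3g",
        best.lambda1, best.lambda2, best.nu, best.kappa,
    )
    return best


def _truth_permutation(truth_beta: np.ndarray, est_beta: np.ndarray) -> np.ndarray:
    """inv[j] = truth component matching fitted component j (mean curves)."""
    perm = match_components(truth_beta[:, 0, :], est_beta[:, 0, :])
    inv = np.empty(perm.size, dtype=int)
    inv[perm] = np.arange(perm.size)
    return inv


def coverage_study(
    sim: SimConfig,
    config: FitConfig,
    n: int,
    n_reps: int,
    B: int,
    seed: int,
    alpha: float = 0.05,
) -> float:
    """Empirical pointwise coverage of the (1 - alpha) bootstrap bands.

    For each replicate: generate, fit at the tuned config, run B warm-started
    multiplier-bootstrap refits, and count (grid point, coefficient) pairs
    whose band covers the generating curve.  Returns the overall fraction.
    """
    t_grid = np.linspace(0.0, 1.0, N_GRID)
    truth_c = truth_curves(sim, t_grid)
    covered, total = 0, 0
    for rep in range(n_reps):
        study, _ = generate(sim, n, seed + 1000 * rep)
        fit = fit_em(study, config)
        bands, eff_B = bootstrap_bands(
            study, fit, config, B=B, alpha=alpha, seed=seed + rep, t_grid=t_grid
        )
        inv = _truth_permutation(truth_c["beta"], fit.curves(t_grid)["beta"])
        for band in bands:
            tv = truth_c[band.kind][inv[band.subtype], band.index]
            covered += int(np.sum((tv >= band.lower) & (tv <= band.upper)))
            total += tv.size
        logger.info("coverage rep %d: eff_B=%d running=%.3f", rep, eff_B, covered / total)
    return covered / total


def imse_study(
    sim: SimConfig, config: FitConfig, ns: tuple, n_reps: int, seed: int
) -> dict:
    """IMSE of every coefficient curve at each sample size, matched seeds.

    Returns {n: {"beta": (K, P+1), "rho": (K, M)}}; replicate d at every n
    uses the same generator seed so the comparison across n is paired.
    """
    t_grid = np.linspace(0.0, 1.0, N_GRID)
    truth_c = truth_curves(sim, t_grid)
    out = {}
    for n in ns:
        estimates = []
        for rep in range(n_reps):
            study, _ = generate(sim, n, seed + 1000 * rep)
            fit = fit_em(study, config)
            estimates.append(fit.curves(t_grid))
        out[n] = imse(estimates, truth_c, t_grid)
    return out


def selection_study(
    sim: SimConfig, config: FitConfig, n: int, n_seeds: int, seed: int
) -> list:
    """FDR and TDR of the selected feature set over independent replicates."""
    results = []
    for rep in range(n_seeds):
        study, truth = generate(sim, n, seed + 1000 * rep)
        fit = fit_em(study, config)
        results.append(fdr_tdr(fit.selected_features, truth["informative"]))
    return results


def scenario1_tuned_config(seed: int, n_tune: int = 500) -> FitConfig:
    """Convenience: tune the scenario-1 study once and return the config."""
    sim = scenario_preset(1)
    return tune_on_replicate(sim, n_tune, seed)
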