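"""Evaluation metrics and downstream effect summaries.

Covers simulation-study metrics (integrated mean squared error of the fitted
coefficient curves, empirical confidence-band coverage, feature-selection
FDR/TDR, clustering agreement) and the applied summaries (interval-averaged
time-varying effects, per-feature odds ratios).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score


def match_components(ref_curves: np.ndarray, new_curves: np.ndarray) -> np.ndarray:
    """Permutation aligning components of ``new`` to ``ref`` by curve distance.

    Both arguments are (K, G) mean-trajectory matrices on a common grid; the
    assignment minimizes the total integrated squared distance.  Returns
    ``perm`` such that new_curves[perm[k]] corresponds to ref_curves[k].
    """
    ref = np.asarray(ref_curves, dtype=float)
    new = np.asarray(new_curves, dtype=float)
    cost = ((ref[:, None, :] - new[None, :, :]) ** 2).mean(axis=2)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(ref.shape[0], dtype=int)
    perm[rows] = cols
    return perm


def _align_estimate(est: dict, truth: dict) -> dict:
    perm = match_components(truth["beta"][:, 0, :], est["beta"][:, 0, :])
    return {"beta": est["beta"][perm], "rho": est["rho"][perm]}


def imse(estimates: list, truth: dict, t_grid: np.ndarray) -> dict:
    """Replicate-averaged integrated squared error of every coefficient curve.

    ``estimates`` is a list (over replicates) of {"beta": (K, P+1, G),
    "rho": (K, M, G)} curve sets on ``t_grid``; ``truth`` has the same
    structure.  Components are aligned to the truth by nearest mean curve
    before scoring; the integral uses the trapezoid rule on the grid.
    Returns {"beta": (K, P+1), "rho": (K, M)}.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    acc_b = np.zeros(truth["beta"].shape[:2])
    acc_r = np.zeros(truth["rho"].shape[:2])
    for est in estimates:
        if est["beta"].shape[-1] != t_grid.size:
            raise ValueError("estimate grid does not match t_grid")
        al = _align_estimate(est, truth)
        acc_b += np.trapezoid((truth["beta"] - al["beta"]) ** 2, t_grid, axis=2)
        acc_r += np.trapezoid((truth["rho"] - al["rho"]) ** 2, t_grid, axis=2)
    n = len(estimates)
    return {"beta": acc_b / n, "rho": acc_r / n}


def empirical_coverage(lower: np.ndarray, upper: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of (replicate, grid-point) pairs with the truth inside the band.

    ``lower`` and ``upper`` broadcast against ``truth`` (typically lower/upper
    are (R, ..., G) and truth (..., G)).
    """
    inside = (np.asarray(truth) >= np.asarray(lower)) & (np.asarray(truth) <= np.asarray(upper))
    return float(np.mean(inside))


def fdr_tdr(selected, informative) -> tuple[float, float]:
    """False and true discovery rates of a selected feature set.

    FDR = |selected \\ informative| / |selected| (0 for an empty selection);
    TDR = |selected & informative| / |informative|.
    """
    sel = set(int(j) for j in selected)
    inf = set(int(j) for j in informative)
    fdr = len(sel - inf) / len(sel) if sel else 0.0
    tdr = len(sel & inf) / len(inf) if inf else 0.0
    return fdr, tdr


def interval_average_effect(
    t_grid: np.ndarray, values: np.ndarray, t1: float, t2: float
) -> float:
    """Normalized integral (t2-t1)^{-1} int_{t1}^{t2} curve(t) dt.

    Trapezoid rule on the stored grid restricted to [t1, t2], with linear
    interpolation at the interval boundaries.
    """
    if not t1 < t2:
        raise ValueError("need t1 < t2")
    t_grid = np.asarray(t_grid, dtype=float)
    values = np.asarray(values, dtype=float)
    if t2 < t_grid[0] or t1 > t_grid[-1]:
        raise ValueError("interval does not overlap the curve domain")
    t1, t2 = max(t1, t_grid[0]), min(t2, t_grid[-1])
    inner = (t_grid > t1) & (t_grid < t2)
    ts = np.concatenate([[t1], t_grid[inner], [t2]])
    vs = np.concatenate([[np.interp(t1, t_grid, values)], values[inner], [np.interp(t2, t_grid, values)]])
    return float(np.trapezoid(vs, ts) / (t2 - t1))


def odds_ratios(fit, reference: int = 0) -> pd.DataFrame:
    """Per-feature odds ratios exp(gamma_kq) of each subtype vs the reference.

    Only the selected features appear; the reference subtype (canonical
    subtype 1, for which gamma = 0) is omitted from the columns.
    """
    if reference != 0:
        raise ValueError("the identifiability gauge fixes subtype 1 as reference")
    sel = np.asarray(fit.selected_features, dtype=int)
    K = fit.params.K
    data = {
        f"OR_subtype{k+1}": np.exp(fit.params.gamma[k, sel + 1]) for k in range(1, K)
    }
    return pd.DataFrame(data, index=[f"feature_{j}" for j in sel])


def label_agreement(labels_a, labels_b) -> float:
    """Adjusted Rand index between two hard labelings (permutation-invariant)."""
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings differ in length")
    return float(adjusted_rand_score(a, b))
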