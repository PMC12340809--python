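"""Synthetic-data generator with known truths.

Emulates the simulation design used to validate the method: K = 3 subtypes
assigned by a multinomial logistic model on high-dimensional omics features
(a small informative set plus many noise features, organized into pathways),
and longitudinal outcomes generated from subtype-specific smooth mean curves
with time-varying effects of P = 2 static and M = 1 longitudinal covariates,
Gaussian random intercepts and noise.

Two presets are shipped:

* Scenario 1 -- Q = 110 features, 10 informative, L = 6 pathways (one
  all-informative pathway of size 10, five noise pathways of size 20);
* Scenario 2 -- Q = 520 features, 20 informative, L = 7 pathways (two
  informative pathways of size 10, five noise pathways of size 100).

All omics features are standard normal a priori; subtype labels are drawn
from the multinomial logistic model with ``gamma_true``, so conditional on
subtype the informative features have class-shifted means (the
class-separating structure) while noise features stay standard normal.  The
mean-trajectory and static-effect truths are linear combinations of a cubic
B-spline basis on [0, 1]; the longitudinal-covariate effects rho_1k(t) are
linear for two subtypes and quadratic for the third.  Every truth is exposed
on :class:`SimConfig` so alternative generating values can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import LongStudy
from .splines import SplineBasis, build_basis, eval_curve

TRUTH_NB = 6  # basis size of the generating curves
TRUTH_DEGREE = 3


def _truth_basis() -> SplineBasis:
    return build_basis(0.0, 1.0, nb=TRUTH_NB, degree=TRUTH_DEGREE)


# generating spline coefficients: rows k = 1..3 (resilient / late / rapid)
_THETA_TRUE = np.array(
    [
        [  # k = 1: stable high trajectory, weak covariate effects
            [2.0, 2.0, 2.1, 2.0, 1.9, 1.9],
            [0.1, 0.1, 0.2, 0.2, 0.1, 0.1],
            [0.0, 0.2, 0.4, 0.4, 0.2, 0.0],
        ],
        [  # k = 2: preserved early, late decline
            [1.5, 1.5, 1.4, 1.0, 0.3, -0.5],
            [0.5, 0.3, 0.0, -0.3, -0.5, -0.6],
            [-0.5, -0.2, 0.2, 0.4, 0.5, 0.6],
        ],
        [  # k = 3: low baseline, rapid decline
            [1.0, 0.4, -0.4, -1.2, -2.0, -2.8],
            [-0.3, -0.4, -0.6, -0.8, -0.9, -1.0],
            [0.6, 0.5, 0.3, 0.0, -0.3, -0.5],
        ],
    ]
)

# rho_1k(t) polynomial coefficients, ascending order: linear, linear, quadratic
_RHO_POLY = [np.array([0.0, 0.5]), np.array([0.8, -0.6]), np.array([-0.4, 2.0, -1.6])]

GAMMA_SIGNAL = 1.2  # logistic coefficient on each informative feature
GAMMA_INTERCEPT = -0.9  # intercepts of subtypes 2 and 3 (balances frequencies)


@dataclass
class SimConfig:
    """Generating model for one simulation scenario.

    ``pathway_layout`` is a list of (size, n_informative) pairs; informative
    features occupy the leading positions of their pathway.  ``gamma_true``
    is (K, Q+1) with the identifiability gauge gamma_1 = 0.
    """

    pathway_layout: list
    gamma_true: np.ndarray
    theta_true: np.ndarray = field(default_factory=lambda: _THETA_TRUE.copy())
    rho_poly: list = field(default_factory=lambda: [c.copy() for c in _RHO_POLY])
    sigma_eps: np.ndarray = field(default_factory=lambda: np.full(3, 0.5))
    sigma_alpha: np.ndarray = field(default_factory=lambda: np.full(3, 0.5))
    visits_min: int = 4
    visits_max: int = 8

    @property
    def K(self) -> int:
        return self.theta_true.shape[0]

    @property
    def P(self) -> int:
        return self.theta_true.shape[1] - 1

    @property
    def M(self) -> int:
        return 1

    @property
    def Q_total(self) -> int:
        return sum(size for size, _ in self.pathway_layout)

    @property
    def informative(self) -> np.ndarray:
        """0-based indices of the informative features."""
        idx, start = [], 0
        for size, n_inf in self.pathway_layout:
            idx.extend(range(start, start + n_inf))
            start += size
        return np.asarray(idx, dtype=int)

    def pathway_groups(self) -> dict:
        groups, start = {}, 0
        for l, (size, _) in enumerate(self.pathway_layout, start=1):
            groups[f"pathway_{l}"] = np.arange(start, start + size)
            start += size
        return groups


def _default_gamma(layout: list) -> np.ndarray:
    """gamma_true: subtype 2 loads on the first half of the informative set,
    subtype 3 on the second half, both with coefficient GAMMA_SIGNAL."""
    Q = sum(size for size, _ in layout)
    informative, start = [], 0
    for size, n_inf in layout:
        informative.extend(range(start, start + n_inf))
        start += size
    informative = np.asarray(informative)
    half = len(informative) // 2
    gamma = np.zeros((3, Q + 1))
    gamma[1, 0] = gamma[2, 0] = GAMMA_INTERCEPT
    gamma[1, informative[:half] + 1] = GAMMA_SIGNAL
    gamma[2, informative[half:] + 1] = GAMMA_SIGNAL
    return gamma


def scenario_preset(which: int) -> SimConfig:
    """Presets for the two simulation scenarios (see module docstring)."""
    if which == 1:
        layout = [(10, 10)] + [(20, 0)] * 5
    elif which == 2:
        layout = [(10, 10), (10, 10)] + [(100, 0)] * 5
    else:
        raise ValueError("scenario must be 1 or 2")
    return SimConfig(pathway_layout=layout, gamma_true=_default_gamma(layout))


def truth_curves(config: SimConfig, t_grid: np.ndarray) -> dict:
    """Exact generating curves on a grid: {"beta": (K, P+1, G), "rho": (K, 1, G)}."""
    t_grid = np.asarray(t_grid, dtype=float)
    basis = _truth_basis()
    K, P1, _ = config.theta_true.shape
    beta = np.empty((K, P1, t_grid.size))
    for k in range(K):
        for p in range(P1):
            beta[k, p] = eval_curve(basis, config.theta_true[k, p], t_grid)
    rho = np.empty((K, 1, t_grid.size))
    for k in range(K):
        rho[k, 0] = np.polynomial.polynomial.polyval(t_grid, config.rho_poly[k])
    return {"beta": beta, "rho": rho}


def generate(config: SimConfig, n: int, seed: int) -> tuple[LongStudy, dict]:
    """Draw one dataset of n subjects; returns (study, truth).

    Each subject is drawn from its own seeded substream (keyed by
    ``(seed, i)``), so datasets are nested across sample sizes: with the same
    seed, the n = 500 dataset is exactly the first 500 subjects of the
    n = 1000 dataset.  This common-random-numbers design makes paired
    comparisons across sample sizes (e.g. IMSE consistency checks) low
    variance.  ``truth`` carries the subtype labels, the informative index
    set, the generating coefficients and the config itself.
    """
    if n < config.K:
        raise ValueError("need n >= K")
    K, P1, Q = config.K, config.P + 1, config.Q_total
    basis = _truth_basis()

    g1 = np.empty((n, Q + 1))
    g1[:, 0] = 1.0
    X = np.empty((n, P1))
    X[:, 0] = 1.0
    z = np.empty(n, dtype=int)
    times, V, outcomes = [], [], []
    for i in range(n):
        rng = np.random.default_rng((int(seed), i))
        g1[i, 1:] = rng.standard_normal(Q)
        X[i, 1] = float(rng.integers(0, 2))  # binary static covariate
        X[i, 2] = rng.standard_normal()  # continuous static covariate
        Ti = int(rng.integers(config.visits_min, config.visits_max + 1))
        t = np.sort(rng.uniform(0.0, 1.0, size=Ti))
        v = rng.standard_normal((Ti, 1))
        lp = config.gamma_true @ g1[i]
        lp -= lp.max()
        pi = np.exp(lp)
        pi /= pi.sum()
        k = int(rng.choice(K, p=pi))
        z[i] = k
        alpha = rng.standard_normal() * config.sigma_alpha[k]
        B = eval_curve(basis, config.theta_true[k], t)  # (T_i, P+1)
        mean = (B * X[i]).sum(axis=1)
        mean += v[:, 0] * np.polynomial.polynomial.polyval(t, config.rho_poly[k])
        y = alpha + mean + rng.standard_normal(Ti) * config.sigma_eps[k]
        times.append(t)
        V.append(v)
        outcomes.append(y)

    ids = np.array([f"S{i:05d}" for i in range(n)])
    study = LongStudy(
        subject_ids=ids,
        times=times,
        outcomes=outcomes,
        static_covs=X,
        long_covs=V,
        omics=g1,
        feature_names=[f"feat_{j:04d}" for j in range(Q)],
        pathway_groups=config.pathway_groups(),
        meta={"generator": "tpclust.simulate", "seed": int(seed), "omics_standardized": False},
    )
    truth = {
        "z": z,
        "informative": config.informative,
        "gamma_true": config.gamma_true,
        "config": config,
    }
    return study, truth


def write_study_tables(study: LongStudy, truth: dict, outdir: str) -> None:
    """Write the study as the package's text input formats plus a truth JSON."""
    import json
    import os

    import pandas as pd

    os.makedirs(outdir, exist_ok=True)
    rows = []
    for i, sid in enumerate(study.subject_ids):
        for j, t in enumerate(study.times[i]):
            rows.append(
                {
                    "id": sid,
                    "time": t,
                    "y": study.outcomes[i][j],
                    **{f"v{m+1}": study.long_covs[i][j, m] for m in range(study.M)},
                }
            )
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "longitudinal.csv"), index=False)
    static = pd.DataFrame(
        study.static_covs[:, 1:], columns=[f"x{p+1}" for p in range(study.P)]
    )
    static.insert(0, "id", study.subject_ids)
    static.to_csv(os.path.join(outdir, "static.csv"), index=False)
    omics = pd.DataFrame(study.omics[:, 1:], columns=study.feature_names)
    omics.insert(0, "id", study.subject_ids)
    omics.to_csv(os.path.join(outdir, "omics.csv"), index=False)
    with open(os.path.join(outdir, "pathways.gmt"), "w") as fh:
        for name, idx in study.pathway_groups.items():
            members = "\t".join(study.feature_names[j] for j in idx)
            fh.write(f"{name}\tsynthetic pathway\t{members}\n")
    cfg = truth["config"]
    doc = {
        "note": "synthetic generating truths",
        "z": truth["z"].tolist(),
        "informative": truth["informative"].tolist(),
        "gamma_true": truth["gamma_true"].tolist(),
        "theta_true": cfg.theta_true.tolist(),
        "rho_poly": [c.tolist() for c in cfg.rho_poly],
        "sigma_eps": cfg.sigma_eps.tolist(),
        "sigma_alpha": cfg.sigma_alpha.tolist(),
    }
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(doc, fh)
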