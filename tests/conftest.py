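"""Shared fixtures: small synthetic studies and a session-tuned configuration."""

import numpy as np
import pytest

import tpclust as tp
from tpclust.simulate import scenario_preset


def make_tiny_study(n=12, Q=3, M=1, T_range=(2, 4), seed=0, K_groups=None):
    """Hand-rolled small LongStudy with arbitrary (non-model) outcomes."""
    rng = np.random.default_rng(seed)
    times, outcomes, long_covs = [], [], []
    for i in range(n):
        T = int(rng.integers(*T_range))
        t = np.sort(rng.uniform(0, 1, T))
        times.append(t)
        outcomes.append(rng.normal(size=T) + 2.0 * (i % 2))
        long_covs.append(rng.normal(size=(T, M)))
    static = np.column_stack([np.ones(n), rng.integers(0, 2, n), rng.normal(size=n)])
    omics = np.hstack([np.ones((n, 1)), rng.normal(size=(n, Q))])
    groups = K_groups or {"g1": np.arange(0, Q // 2), "g2": np.arange(Q // 2, Q)}
    return tp.LongStudy(
        subject_ids=np.array([f"S{i:03d}" for i in range(n)]),
        times=times,
        outcomes=outcomes,
        static_covs=static,
        long_covs=long_covs,
        omics=omics,
        feature_names=[f"f{j}" for j in range(Q)],
        pathway_groups=groups,
    )


@pytest.fixture
def tiny_study():
    return make_tiny_study()


@pytest.fixture(scope="session")
def scenario1():
    return scenario_preset(1)


@pytest.fixture(scope="session")
def small_sim_study(scenario1):
    """One moderate scenario-1 dataset reused across tests."""
    study, truth = tp.generate(scenario1, 150, 0)
    return study, truth


@pytest.fixture(scope="session")
def small_fit(small_sim_study):
    """A converged fit on the small scenario-1 dataset."""
    study, _ = small_sim_study
    cfg = tp.FitConfig(K=3, lambda1=8.0, lambda2=12.0, nu=0.1, kappa=0.1,
                       n_restarts=2, seed=0)
    return tp.fit_em(study, cfg)


@pytest.fixture(scope="session")
def tuned_config(scenario1):
    """Penalties tuned once (relaxed-lasso CV on one replicate) and reused."""
    from tpclust.simstudy import tune_on_replicate

    return tune_on_replicate(scenario1, 500, 0)
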