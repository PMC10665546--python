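"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

from phenostates import (
    McmcConfig,
    apply_exclusions,
    compute_aic,
    fit_mhmm,
    inject_missingness,
    relabel_states,
    simulate_dataset,
)
from phenostates.synthetic_cohort import default_config


def random_hmm(rng, K=2, J=2, C=3, T=5):
    """A random small HMM instance for enumeration oracles."""
    gamma = rng.dirichlet(np.ones(K), size=K)
    theta = rng.dirichlet(np.ones(C), size=(K, J))
    init = rng.dirichlet(np.ones(K))
    obs = rng.integers(0, C, size=(T, J))
    return gamma, theta, init, obs


def enumerate_paths_loglik(obs, gamma, theta, init):
    """Brute-force observed-data likelihood by summing over all state paths."""
    import itertools

    K = gamma.shape[0]
    T = obs.shape[0]
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = init[path[0]]
        for t in range(1, T):
            p *= gamma[path[t - 1], path[t]]
        for t in range(T):
            for j in range(obs.shape[1]):
                if obs[t, j] >= 0:
                    p *= theta[path[t], j, obs[t, j]]
        total += p
    return np.log(total)


def enumerate_posterior(obs, gamma, theta, init):
    """Brute-force smoothed posteriors and the best path (lowest-index ties)."""
    import itertools

    K = gamma.shape[0]
    T = obs.shape[0]
    post = np.zeros((T, K))
    best_p, best_path = -1.0, None
    for path in itertools.product(range(K), repeat=T):
        p = init[path[0]]
        for t in range(1, T):
            p *= gamma[path[t - 1], path[t]]
        for t in range(T):
            for j in range(obs.shape[1]):
                if obs[t, j] >= 0:
                    p *= theta[path[t], j, obs[t, j]]
        for t in range(T):
            post[t, path[t]] += p
        if p > best_p:
            best_p, best_path = p, path
    return post / post.sum(axis=1, keepdims=True), np.array(best_path), np.log(best_p)


@pytest.fixture(scope="session")
def recovery_cohort():
    """40 subjects × 90 weeks from the default configuration (fixed seed)."""
    cfg = default_config(n_subjects=40, seed=1)
    panel, cov, truth = simulate_dataset(cfg)
    panel = inject_missingness(panel, cfg)
    filtered, _ = apply_exclusions(panel)
    return cfg, filtered, cov, truth


@pytest.fixture(scope="session")
def recovery_fit(recovery_cohort):
    """The K=3 multilevel fit used by the recovery checks (shared; ~10 s)."""
    _, filtered, _, _ = recovery_cohort
    fit = fit_mhmm(filtered, 3, mcmc=McmcConfig(n_iterations=1500, n_burnin=500, seed=1))
    fit = relabel_states(fit)
    compute_aic(fit)
    return fit
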