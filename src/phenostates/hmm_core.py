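"""Exact inference for a single-subject hidden Markov model with
multivariate categorical emissions.

States and rating categories are 0-based integers throughout this module;
the value :data:`MISSING` (−1) marks a missing symptom rating.  Weeks with
every symptom missing contribute an emission factor of 1 (the observation
is marginalised out); weeks that were removed from the record entirely can
be declared through the ``weeks`` argument, in which case a gap of *g*
skipped weeks is bridged with the (g+1)-step transition matrix Γ^(g+1).

The forward recursion uses scaled (normalised) forward variables with the
per-week scaling factors accumulated into the log-likelihood, which is the
standard numerically stable formulation.
"""

from __future__ import annotations

import warnings

import numpy as np

MISSING = -1

__all__ = [
    "MISSING",
    "emission_logprob",
    "forward_loglik",
    "posterior_state_probs",
    "posterior_joint_probs",
    "viterbi_decode",
    "stationary_init",
]


def _validate(obs: np.ndarray, gamma: np.ndarray, theta: np.ndarray) -> None:
    K = gamma.shape[0]
    if gamma.shape != (K, K):
        raise ValueError("transition matrix must be square")
    if not np.allclose(gamma.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("transition matrix rows must sum to 1")
    if theta.shape[0] != K:
        raise ValueError("emission table first axis must match number of states")
    if not np.allclose(theta.sum(axis=2), 1.0, atol=1e-10):
        raise ValueError("emission probability vectors must sum to 1")
    C = theta.shape[2]
    valid = (obs == MISSING) | ((obs >= 0) & (obs < C))
    if not valid.all():
        raise ValueError("observations must be category indices in [0, C) or MISSING")


def _as_obs(obs) -> np.ndarray:
    arr = np.asarray(obs)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr.astype(np.int64)


def emission_logprob(obs: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Per-week log emission probability under each state.

    Parameters
    ----------
    obs
        Integer array of shape (T, J); entries are rating categories in
        ``0..C-1`` or :data:`MISSING`.
    theta
        Emission table of shape (K, J, C): ``theta[k, j, c]`` is
        P(rating of symptom j = c | state k).  Symptoms are conditionally
        independent given the state.

    Returns
    -------
    ndarray of shape (T, K) with log P(observed ratings at week t | state k);
    missing cells contribute 0 to the sum (factor 1).
    """
    obs = _as_obs(obs)
    T, J = obs.shape
    K = theta.shape[0]
    out = np.zeros((T, K))
    with np.errstate(divide="ignore"):
        logtheta = np.log(theta)
    for j in range(J):
        col = obs[:, j]
        seen = col != MISSING
        if not seen.any():
            continue
        out[seen] += logtheta[:, j, col[seen]].T
    return out


def _step_matrices(gamma: np.ndarray, weeks, T: int) -> list[np.ndarray]:
    """Transition matrix for each step t-1 → t, bridging week gaps with powers."""
    if weeks is None:
        return [gamma] * (T - 1)
    weeks = np.asarray(weeks, dtype=np.int64)
    if weeks.shape[0] != T:
        raise ValueError("weeks must have one entry per observation row")
    if np.any(np.diff(weeks) < 1):
        raise ValueError("weeks must be strictly increasing")
    powers: dict[int, np.ndarray] = {1: gamma}
    mats = []
    for g in np.diff(weeks):
        g = int(g)
        if g not in powers:
            powers[g] = np.linalg.matrix_power(gamma, g)
        mats.append(powers[g])
    return mats


def _prepare(obs, gamma, theta, init, weeks):
    obs = _as_obs(obs)
    gamma = np.asarray(gamma, dtype=float)
    theta = np.asarray(theta, dtype=float)
    _validate(obs, gamma, theta)
    if init is None:
        init = stationary_init(gamma)
    init = np.asarray(init, dtype=float)
    if not np.isclose(init.sum(), 1.0, atol=1e-8):
        raise ValueError("initial distribution must sum to 1")
    T = obs.shape[0]
    logB = emission_logprob(obs, theta)
    return obs, gamma, theta, init, logB, _step_matrices(gamma, weeks, T)


def stationary_init(gamma: np.ndarray) -> np.ndarray:
    """Stationary distribution of Γ used as the default initial distribution.

    Solved as the linear system πΓ = π, Σπ = 1 (least squares, robust to the
    rank deficiency of Γᵀ − I).
    """
    K = gamma.shape[0]
    A = np.vstack([gamma.T - np.eye(K), np.ones((1, K))])
    b = np.zeros(K + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _scaled_forward(init, logB, step_mats):
    """Scaled forward pass; returns (alpha, per-week log scaling factors)."""
    T, K = logB.shape
    offs = logB.max(axis=1)
    if np.isneginf(offs).any():  # some week impossible under every state
        return None, None
    B = np.exp(logB - offs[:, None])
    alpha = np.empty((T, K))
    logc = np.empty(T)
    a = init * B[0]
    s = a.sum()
    if s <= 0.0:
        return None, None
    alpha[0] = a / s
    logc[0] = np.log(s) + offs[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ step_mats[t - 1]) * B[t]
        s = a.sum()
        if s <= 0.0:
            return None, None
        alpha[t] = a / s
        logc[t] = np.log(s) + offs[t]
    return alpha, logc


def forward_loglik(obs, gamma, theta, init=None, weeks=None) -> float:
    """Observed-data log-likelihood of one subject's rating sequence.

    A gap of g skipped weeks (from ``weeks``) is bridged with Γ^(g+1); a
    rating sequence whose probability is zero under every state returns
    ``-inf`` with a warning.
    """
    _, gamma, _, init, logB, mats = _prepare(obs, gamma, theta, init, weeks)
    _, logc = _scaled_forward(init, logB, mats)
    if logc is None:
        warnings.warn("observation has zero probability under all states")
        return -np.inf
    return float(logc.sum())


def posterior_state_probs(obs, gamma, theta, init=None, weeks=None) -> np.ndarray:
    """Smoothed per-week posterior state probabilities (forward–backward)."""
    _, gamma, _, init, logB, mats = _prepare(obs, gamma, theta, init, weeks)
    alpha, logc = _scaled_forward(init, logB, mats)
    if logc is None:
        warnings.warn("observation has zero probability under all states")
        raise FloatingPointError("zero-probability observation sequence")
    T, K = logB.shape
    B = np.exp(logB - logB.max(axis=1, keepdims=True))
    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        b = mats[t] @ (B[t + 1] * beta[t + 1])
        beta[t] = b / b.max()
    post = alpha * beta
    return post / post.sum(axis=1, keepdims=True)


def posterior_joint_probs(obs, gamma, theta, init=None, weeks=None) -> np.ndarray:
    """Pairwise posteriors P(state t = i, state t+1 = j | data), shape (T-1, K, K).

    Consistency check: summing over j recovers the week-t smoothed posterior.
    """
    _, gamma, _, init, logB, mats = _prepare(obs, gamma, theta, init, weeks)
    alpha, logc = _scaled_forward(init, logB, mats)
    if logc is None:
        raise FloatingPointError("zero-probability observation sequence")
    T, K = logB.shape
    B = np.exp(logB - logB.max(axis=1, keepdims=True))
    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        b = mats[t] @ (B[t + 1] * beta[t + 1])
        beta[t] = b / b.max()
    out = np.empty((T - 1, K, K))
    for t in range(T - 1):
        xi = alpha[t][:, None] * mats[t] * (B[t + 1] * beta[t + 1])[None, :]
        out[t] = xi / xi.sum()
    return out


def viterbi_decode(obs, gamma, theta, init=None, weeks=None):
    """Maximum-probability state path.

    Returns ``(path, log_score)`` where ``path`` is a 0-based state index per
    observed week.  Ties are broken toward the lowest state index.
    """
    _, gamma, _, init, logB, mats = _prepare(obs, gamma, theta, init, weeks)
    T, K = logB.shape
    with np.errstate(divide="ignore"):
        loginit = np.log(init)
        logmats = [np.log(m) for m in mats]
    delta = loginit + logB[0]
    back = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        cand = delta[:, None] + logmats[t - 1]
        back[t] = np.argmax(cand, axis=0)  # argmax → first (lowest) index on ties
        delta = cand[back[t], np.arange(K)] + logB[t]
    path = np.empty(T, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    score = float(delta[path[-1]])
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path, score
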