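"""Bayesian estimation of the multilevel hidden Markov model.

Model
-----
Each subject i carries their own transition matrix Γ_i and emission table
θ_i, parameterised on baseline-category multinomial logits (see
:mod:`phenostates.mlogit`).  Subject logits are normal random effects
around group-level means:

    η_i,km ~ N(μ_km, σ²_trans,k)      (transition row k, destination m)
    λ_i,kjc ~ N(ν_kjc, σ²_emis,k)     (state k, symptom j, category c)

with diffuse normal priors on the group means and conjugate inverse-gamma
priors on the state-specific random-effect variances.  Subjects are
exchangeable; covariates enter only post hoc.

Sampler
-------
A Metropolis-within-Gibbs scheme alternating

(a) per-subject latent state paths by forward-filtering backward-sampling
    over the full weekly grid (weeks with no ratings contribute emission
    factor 1, so removed weeks are marginalised exactly);
(b) per-subject transition rows and emission blocks by random-walk
    Metropolis on the complete-data (count) likelihood, with proposal
    scales adapted during burn-in toward a 23–44% acceptance band and
    frozen afterwards;
(c) group means and random-effect variances by conjugate updates, followed
    by an interweaving (non-centred) Metropolis move that shifts a group
    mean together with every subject's logits while holding the subject
    deviations fixed — the random-effect density is invariant under this
    move, so it is accepted on the complete-data likelihood plus the group
    prior.  This decouples the group means from the tightly coupled
    centred parameterisation and greatly improves their effective sample
    size when the random-effect variances are small.

State labels are not identified by the likelihood; :func:`relabel_states`
maps every draw to the canonical order of increasing mean symptom
endorsement P(rating ≥ subclinical | state).
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hmm_core import MISSING, forward_loglik
from .io_tables import PanelDataset
from .mlogit import logits_to_probs, probs_to_logits

logger = logging.getLogger(__name__)

__all__ = [
    "PriorSpec",
    "McmcConfig",
    "MHMMFit",
    "ModelSelectionTable",
    "fit_mhmm",
    "relabel_states",
    "compute_aic",
    "select_num_states",
    "convergence_diagnostics",
    "canonical_state_labels",
    "save_fit",
    "load_fit",
]


@dataclass
class PriorSpec:
    """Priors for the group-level model.

    ``mu_mean``/``mu_sd`` give the normal prior on every group-level logit
    (diffuse by default); the random-effect variances get conjugate
    inverse-gamma(shape, scale) priors, weakly informative with prior mean
    scale/(shape−1) = 0.5 on the logit scale.
    """

    mu_mean: float = 0.0
    mu_sd: float = 5.0
    re_var_shape: float = 2.0
    re_var_scale: float = 0.5

    def validate(self) -> None:
        if self.mu_sd <= 0 or self.re_var_shape <= 0 or self.re_var_scale <= 0:
            raise ValueError("prior scales and shapes must be positive")


@dataclass
class McmcConfig:
    n_iterations: int = 1500
    n_burnin: int = 500
    proposal_scale_transition: float = 0.4
    proposal_scale_emission: float = 0.4
    adapt: bool = True
    target_accept: float = 0.35
    seed: int = 0
    n_chains: int = 1

    def validate(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not (0 <= self.n_burnin < self.n_iterations):
            raise ValueError("burn-in must be shorter than the iteration count")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")


def canonical_state_labels(n_states: int) -> list[str]:
    """Names for canonically ordered states (ascending symptom endorsement)."""
    if n_states == 3:
        return ["low", "cognitive_physical", "elevated"]
    return [f"state_{k + 1}" for k in range(n_states)]


@dataclass
class MHMMFit:
    """Posterior draws and bookkeeping for one fitted multilevel HMM."""

    n_states: int
    n_symptoms: int
    n_levels: int
    subject_ids: list
    symptoms: list
    group_trans_logits: np.ndarray  # (S, K, K-1)
    group_emis_logits: np.ndarray  # (S, K, J, C-1)
    re_var_trans: np.ndarray  # (S, K)
    re_var_emis: np.ndarray  # (S, K)
    subject_trans_logits: np.ndarray  # (S, n, K, K-1)
    subject_emis_logits: np.ndarray  # (S, n, K, J, C-1)
    loglik_trace: np.ndarray  # (n_iterations,) observed-data loglik at subject params
    acceptance: dict
    mcmc: McmcConfig
    priors: PriorSpec
    obs: np.ndarray  # (n, T, J) full weekly grid, MISSING = -1
    valid_week: np.ndarray  # (n, T)
    state_labels: list = field(default_factory=list)
    relabelled: bool = False
    aic: float | None = None

    def __post_init__(self) -> None:
        if not self.state_labels:
            self.state_labels = [f"state_{k + 1}" for k in range(self.n_states)]

    @property
    def n_draws(self) -> int:
        return self.group_trans_logits.shape[0]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    # -- posterior summaries -------------------------------------------------

    def group_transition_draws(self) -> np.ndarray:
        return logits_to_probs(self.group_trans_logits)

    def group_emission_draws(self) -> np.ndarray:
        return logits_to_probs(self.group_emis_logits)

    def group_transition_mean(self) -> np.ndarray:
        return self.group_transition_draws().mean(axis=0)

    def group_emission_mean(self) -> np.ndarray:
        return self.group_emission_draws().mean(axis=0)

    def subject_transition_means(self) -> np.ndarray:
        if self.subject_trans_logits.shape[0] == 0:
            raise ValueError("subject-level draws were not stored for this fit")
        return logits_to_probs(self.subject_trans_logits).mean(axis=0)

    def subject_emission_means(self) -> np.ndarray:
        if self.subject_emis_logits.shape[0] == 0:
            raise ValueError("subject-level draws were not stored for this fit")
        return logits_to_probs(self.subject_emis_logits).mean(axis=0)

    def posterior_median_group_params(self) -> tuple[np.ndarray, np.ndarray]:
        gamma = logits_to_probs(np.median(self.group_trans_logits, axis=0))
        theta = logits_to_probs(np.median(self.group_emis_logits, axis=0))
        return gamma, theta

    def subject_observations(self, subject_id) -> tuple[np.ndarray, np.ndarray]:
        """Observed rows only, as (obs, weeks) for the likelihood modules."""
        i = self.subject_ids.index(subject_id)
        obs = self.obs[i]
        seen = (obs != MISSING).any(axis=1) & self.valid_week[i]
        return obs[seen], np.flatnonzero(seen) + 1


# ---------------------------------------------------------------------------
# data preparation


def _panel_to_arrays(data: PanelDataset):
    ids = data.subject_ids
    J = len(data.symptoms)
    per = [data.subject_obs(sid) for sid in ids]
    spans = [int(w.max()) for _, w in per]
    T = max(spans)
    obs = np.full((len(ids), T, J), MISSING, dtype=np.int64)
    valid = np.zeros((len(ids), T), dtype=bool)
    for i, ((o, w), span) in enumerate(zip(per, spans)):
        obs[i, w - 1] = o
        valid[i, :span] = True
        if (o != MISSING).any(axis=1).sum() < 2:
            raise ValueError(f"subject {ids[i]!r} has fewer than 2 observed weeks")
    return ids, obs, valid


def _initial_paths(obs: np.ndarray, valid: np.ndarray, K: int) -> np.ndarray:
    """Severity-quantile initial state assignment (orders states by severity).

    Weekly severity is smoothed over neighbouring weeks before binning so
    that rating ties do not produce artificially switchy initial paths (the
    sticky mode is then reachable within a short burn-in even when per-week
    emission information is weak).
    """
    n, T, J = obs.shape
    seen = obs != MISSING
    with np.errstate(invalid="ignore"):
        sev = np.where(seen, obs, 0).sum(axis=2) / np.maximum(seen.sum(axis=2), 1)
    kernel = np.array([0.15, 0.7, 0.15])
    sev = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), 1, sev)
    any_seen = seen.any(axis=2)
    vals = sev[any_seen]
    # jitter deterministic on rank to break mass ties at identical severities
    order = np.argsort(vals, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(vals.size)
    bins = np.minimum((ranks * K) // max(vals.size, 1), K - 1)
    paths = np.zeros((n, T), dtype=np.int64)
    paths[any_seen] = bins
    # fill unobserved weeks from the nearest observed week (forward then back)
    for i in range(n):
        idx = np.flatnonzero(any_seen[i])
        if idx.size == 0:
            continue
        filled = np.interp(np.arange(T), idx, paths[i, idx])
        paths[i] = np.round(filled).astype(np.int64)
    return paths


def _batched_stationary(gamma: np.ndarray) -> np.ndarray:
    """Stationary distributions of a (n, K, K) stack of transition matrices."""
    n, K, _ = gamma.shape
    A = np.transpose(gamma, (0, 2, 1)) - np.eye(K)[None]
    A[:, -1, :] = 1.0
    b = np.zeros((n, K, 1))
    b[:, -1, 0] = 1.0
    try:
        pi = np.linalg.solve(A, b)[:, :, 0]
    except np.linalg.LinAlgError:
        pi = np.stack([np.linalg.lstsq(A[i], b[i], rcond=None)[0][:, 0] for i in range(n)])
    pi = np.clip(pi, 1e-12, None)
    return pi / pi.sum(axis=1, keepdims=True)


def _emission_logB(obs: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Per-subject-week log emission likelihood, (n, T, K)."""
    n, T, J = obs.shape
    K = theta.shape[1]
    logB = np.zeros((n, T, K))
    logtheta = np.log(theta)  # softmax output is strictly positive
    rows = np.arange(n)[:, None]
    for j in range(J):
        col = obs[:, :, j]
        seen = col != MISSING
        lt = logtheta[:, :, j, :].transpose(0, 2, 1)  # (n, C, K)
        vals = lt[rows, np.where(seen, col, 0), :]  # (n, T, K)
        logB += np.where(seen[:, :, None], vals, 0.0)
    return logB


def _sample_categorical_rows(p: np.ndarray, u: np.ndarray) -> np.ndarray:
    cum = np.cumsum(p, axis=1)
    return (cum < (u * cum[:, -1])[:, None]).sum(axis=1)


def _row_logprobs(eta: np.ndarray) -> np.ndarray:
    """log softmax([0, eta]) along the last axis."""
    full = np.concatenate([np.zeros(eta.shape[:-1] + (1,)), eta], axis=-1)
    m = full.max(axis=-1, keepdims=True)
    return full - m - np.log(np.exp(full - m).sum(axis=-1, keepdims=True))


# ---------------------------------------------------------------------------
# the sampler


def _run_chain(obs, valid, K, C, priors, mcmc, seed, store):
    rng = np.random.default_rng(seed)
    n, T, J = obs.shape
    Km1, Cm1 = K - 1, C - 1
    valid_step = valid[:, :-1] & valid[:, 1:]
    seen = obs != MISSING

    # --- initialisation from a severity-quantile path; diagonal pseudocounts
    # start the transition logits in the persistent regime the weekly data
    # typically favour ---
    paths = _initial_paths(obs, valid, K)
    t_counts = np.full((n, K, K), 0.5) + 5.0 * np.eye(K)
    e_counts = np.full((n, K, J, C), 0.5)
    np.add.at(
        t_counts.reshape(n, -1),
        (np.repeat(np.arange(n), T - 1)[valid_step.ravel()],
         (paths[:, :-1] * K + paths[:, 1:]).ravel()[valid_step.ravel()]),
        1.0,
    )
    e_flat = e_counts.reshape(n, -1)  # contiguous view over (K, J, C)
    for j in range(J):
        sj = seen[:, :, j]
        np.add.at(
            e_flat,
            (np.repeat(np.arange(n), T)[sj.ravel()],
             ((paths * J + j) * C + obs[:, :, j]).ravel()[sj.ravel()]),
            1.0,
        )
    eta_t = probs_to_logits(t_counts / t_counts.sum(axis=2, keepdims=True))
    eta_e = probs_to_logits(e_counts / e_counts.sum(axis=3, keepdims=True))
    mu_t = eta_t.mean(axis=0)
    mu_e = eta_e.mean(axis=0)
    var_t = np.full(K, 0.25)
    var_e = np.full(K, 0.25)

    scale_t = np.full(K, mcmc.proposal_scale_transition)
    scale_e = np.full(K, mcmc.proposal_scale_emission)
    scale_mt = np.full(K, mcmc.proposal_scale_transition / np.sqrt(max(n, 1)))
    scale_me = np.full(K, mcmc.proposal_scale_emission / np.sqrt(max(n, 1)))
    acc_t_post = np.zeros(K)
    acc_e_post = np.zeros(K)
    n_post = 0

    S = mcmc.n_iterations - mcmc.n_burnin
    draws = {
        "mu_t": np.empty((S, K, Km1)),
        "mu_e": np.empty((S, K, J, Cm1)),
        "var_t": np.empty((S, K)),
        "var_e": np.empty((S, K)),
        "eta_t": np.empty((S, n, K, Km1)) if store else None,
        "eta_e": np.empty((S, n, K, J, Cm1)) if store else None,
    }
    loglik = np.empty(mcmc.n_iterations)

    prior_prec = 1.0 / priors.mu_sd**2
    subj_rows = np.arange(n)

    for it in range(mcmc.n_iterations):
        gamma = logits_to_probs(eta_t) if K > 1 else np.ones((n, 1, 1))
        theta = logits_to_probs(eta_e)

        # (a) forward-filtering backward-sampling of latent paths
        logB = _emission_logB(obs, theta)
        offs = logB.max(axis=2)
        B = np.exp(logB - offs[:, :, None])
        init = _batched_stationary(gamma) if K > 1 else np.ones((n, 1))
        alpha = np.empty((n, T, K))
        a = init * B[:, 0]
        s = a.sum(axis=1)
        alpha[:, 0] = a / s[:, None]
        ll = np.log(s) + offs[:, 0]
        for t in range(1, T):
            a = np.einsum("nk,nkl->nl", alpha[:, t - 1], gamma) * B[:, t]
            s = a.sum(axis=1)
            alpha[:, t] = a / s[:, None]
            ll += np.log(s) + offs[:, t]
        loglik[it] = ll.sum()

        u = rng.random((n, T))
        paths[:, T - 1] = _sample_categorical_rows(alpha[:, T - 1], u[:, T - 1])
        for t in range(T - 2, -1, -1):
            p = alpha[:, t] * gamma[subj_rows, :, paths[:, t + 1]]
            paths[:, t] = _sample_categorical_rows(p, u[:, t])

        # complete-data counts (padding weeks beyond a subject's span excluded)
        t_counts.fill(0.0)
        np.add.at(
            t_counts.reshape(n, -1),
            (np.repeat(subj_rows, T - 1)[valid_step.ravel()],
             (paths[:, :-1] * K + paths[:, 1:]).ravel()[valid_step.ravel()]),
            1.0,
        )
        e_counts.fill(0.0)
        for j in range(J):
            sj = seen[:, :, j]
            np.add.at(
                e_flat,
                (np.repeat(subj_rows, T)[sj.ravel()],
                 ((paths * J + j) * C + obs[:, :, j]).ravel()[sj.ravel()]),
                1.0,
            )

        # (b) random-walk Metropolis on subject logits
        if K > 1:
            prop = eta_t + scale_t[None, :, None] * rng.standard_normal(eta_t.shape)
            lp_cur = (t_counts * _row_logprobs(eta_t)).sum(axis=2)
            lp_new = (t_counts * _row_logprobs(prop)).sum(axis=2)
            pr_cur = -0.5 * ((eta_t - mu_t[None]) ** 2).sum(axis=2) / var_t[None]
            pr_new = -0.5 * ((prop - mu_t[None]) ** 2).sum(axis=2) / var_t[None]
            acc = np.log(rng.random((n, K))) < (lp_new + pr_new - lp_cur - pr_cur)
            eta_t = np.where(acc[:, :, None], prop, eta_t)
            rate_t = acc.mean(axis=0)
        else:
            rate_t = np.ones(K)

        prop = eta_e + scale_e[None, :, None, None] * rng.standard_normal(eta_e.shape)
        lp_cur = (e_counts * _row_logprobs(eta_e)).sum(axis=3)
        lp_new = (e_counts * _row_logprobs(prop)).sum(axis=3)
        pr_cur = -0.5 * ((eta_e - mu_e[None]) ** 2).sum(axis=3) / var_e[None, :, None]
        pr_new = -0.5 * ((prop - mu_e[None]) ** 2).sum(axis=3) / var_e[None, :, None]
        acc_e = np.log(rng.random((n, K, J))) < (lp_new + pr_new - lp_cur - pr_cur)
        eta_e = np.where(acc_e[:, :, :, None], prop, eta_e)
        rate_e = acc_e.mean(axis=(0, 2))

        # (c) conjugate group updates
        if K > 1:
            prec = n / var_t[:, None] + prior_prec
            mean = (eta_t.sum(axis=0) / var_t[:, None] + priors.mu_mean * prior_prec) / prec
            mu_t = mean + rng.standard_normal(mu_t.shape) / np.sqrt(prec)
            ss = ((eta_t - mu_t[None]) ** 2).sum(axis=(0, 2))
            shape = priors.re_var_shape + 0.5 * n * Km1
            var_t = 1.0 / rng.gamma(shape, 1.0 / (priors.re_var_scale + 0.5 * ss))
        prec = n / var_e[:, None, None] + prior_prec
        mean = (eta_e.sum(axis=0) / var_e[:, None, None] + priors.mu_mean * prior_prec) / prec
        mu_e = mean + rng.standard_normal(mu_e.shape) / np.sqrt(prec)
        ss = ((eta_e - mu_e[None]) ** 2).sum(axis=(0, 2, 3))
        shape = priors.re_var_shape + 0.5 * n * J * Cm1
        var_e = 1.0 / rng.gamma(shape, 1.0 / (priors.re_var_scale + 0.5 * ss))

        # interweaving: shift a group mean and all subject logits together,
        # deviations fixed; random-effect density cancels in the ratio
        if K > 1:
            eps = scale_mt[:, None] * rng.standard_normal(mu_t.shape)
            lp_cur = (t_counts * _row_logprobs(eta_t)).sum(axis=(0, 2))
            lp_new = (t_counts * _row_logprobs(eta_t + eps[None])).sum(axis=(0, 2))
            pr_cur = -0.5 * prior_prec * ((mu_t - priors.mu_mean) ** 2).sum(axis=1)
            pr_new = -0.5 * prior_prec * ((mu_t + eps - priors.mu_mean) ** 2).sum(axis=1)
            acc_m = np.log(rng.random(K)) < (lp_new + pr_new - lp_cur - pr_cur)
            mu_t = np.where(acc_m[:, None], mu_t + eps, mu_t)
            eta_t = np.where(acc_m[None, :, None], eta_t + eps[None], eta_t)
            rate_mt = acc_m.astype(float)
        else:
            rate_mt = np.ones(K)
        eps = scale_me[:, None, None] * rng.standard_normal(mu_e.shape)
        lp_cur = (e_counts * _row_logprobs(eta_e)).sum(axis=(0, 3))  # (K, J)
        lp_new = (e_counts * _row_logprobs(eta_e + eps[None])).sum(axis=(0, 3))
        pr_cur = -0.5 * prior_prec * ((mu_e - priors.mu_mean) ** 2).sum(axis=2)
        pr_new = -0.5 * prior_prec * ((mu_e + eps - priors.mu_mean) ** 2).sum(axis=2)
        acc_me = np.log(rng.random((K, J))) < (lp_new + pr_new - lp_cur - pr_cur)
        mu_e = np.where(acc_me[:, :, None], mu_e + eps, mu_e)
        eta_e = np.where(acc_me[None, :, :, None], eta_e + eps[None], eta_e)
        rate_me = acc_me.mean(axis=1)

        # proposal adaptation (burn-in only; frozen afterwards)
        if mcmc.adapt and it < mcmc.n_burnin:
            step = 1.0 / (1.0 + it) ** 0.6
            scale_t = np.clip(scale_t * np.exp(step * (rate_t - mcmc.target_accept)), 1e-3, 10.0)
            scale_e = np.clip(scale_e * np.exp(step * (rate_e - mcmc.target_accept)), 1e-3, 10.0)
            scale_mt = np.clip(scale_mt * np.exp(step * (rate_mt - mcmc.target_accept)),
                               1e-4, 10.0)
            scale_me = np.clip(scale_me * np.exp(step * (rate_me - mcmc.target_accept)),
                               1e-4, 10.0)

        if it >= mcmc.n_burnin:
            s_idx = it - mcmc.n_burnin
            draws["mu_t"][s_idx] = mu_t
            draws["mu_e"][s_idx] = mu_e
            draws["var_t"][s_idx] = var_t
            draws["var_e"][s_idx] = var_e
            if store:
                draws["eta_t"][s_idx] = eta_t
                draws["eta_e"][s_idx] = eta_e
            acc_t_post += rate_t
            acc_e_post += rate_e
            n_post += 1

    acceptance = {
        "transition": acc_t_post / max(n_post, 1),
        "emission": acc_e_post / max(n_post, 1),
        "proposal_scale_transition": scale_t,
        "proposal_scale_emission": scale_e,
    }
    return draws, loglik, acceptance


def fit_mhmm(
    data: PanelDataset,
    n_states: int,
    priors: PriorSpec | None = None,
    mcmc: McmcConfig | None = None,
    store_subject_draws: bool = True,
) -> MHMMFit:
    """Fit the multilevel HMM by MCMC; deterministic given ``mcmc.seed``.

    Multiple chains (``mcmc.n_chains``) are run sequentially with seeds
    ``seed, seed+1, ...`` and their post-burn-in draws concatenated.
    """
    priors = priors or PriorSpec()
    mcmc = mcmc or McmcConfig()
    priors.validate()
    mcmc.validate()
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    ids, obs, valid = _panel_to_arrays(data)
    C = len(_levels_of(data))
    chains = []
    for c in range(mcmc.n_chains):
        chains.append(_run_chain(obs, valid, n_states, C, priors, mcmc, mcmc.seed + c,
                                 store_subject_draws))
    draws = {
        k: np.concatenate([ch[0][k] for ch in chains])
        for k in chains[0][0]
        if chains[0][0][k] is not None
    }
    loglik = np.concatenate([ch[1] for ch in chains])
    if not np.isfinite(loglik).all():
        raise FloatingPointError("non-finite likelihood encountered during sampling")
    acceptance = chains[-1][2]
    n, T, J = obs.shape
    empty_t = np.empty((0, n, n_states, n_states - 1))
    empty_e = np.empty((0, n, n_states, J, C - 1))
    fit = MHMMFit(
        n_states=n_states,
        n_symptoms=J,
        n_levels=C,
        subject_ids=ids,
        symptoms=list(data.symptoms),
        group_trans_logits=draws["mu_t"],
        group_emis_logits=draws["mu_e"],
        re_var_trans=draws["var_t"],
        re_var_emis=draws["var_e"],
        subject_trans_logits=draws.get("eta_t", empty_t),
        subject_emis_logits=draws.get("eta_e", empty_e),
        loglik_trace=loglik,
        acceptance=acceptance,
        mcmc=mcmc,
        priors=priors,
        obs=obs,
        valid_week=valid,
    )
    return fit


def _levels_of(data: PanelDataset) -> list[int]:
    vals = pd.concat([data.df[s].dropna() for s in data.symptoms])
    top = int(vals.max()) if len(vals) else 3
    return list(range(1, max(top, 3) + 1))


# ---------------------------------------------------------------------------
# relabelling, AIC, model selection, diagnostics


def relabel_states(fit: MHMMFit) -> MHMMFit:
    """Canonicalise state labels draw by draw.

    Within each draw, states are sorted ascending by the mean over symptoms
    of P(rating ≥ subclinical | state); exact ties keep their prior order
    (stable sort) and are logged.  The permutation is applied consistently
    to transition, emission, variance, and subject-level draws.  Idempotent.
    """
    out = copy.copy(fit)
    ge = fit.group_emission_draws()  # (S, K, J, C)
    keys = (1.0 - ge[:, :, :, 0]).mean(axis=2)  # (S, K)
    S, K = keys.shape
    if np.any([np.unique(k).size < K for k in keys]):
        logger.info("exact endorsement ties encountered; stable order retained")
    perms = np.argsort(keys, axis=1, kind="stable")

    def permute_trans(logits):
        probs = logits_to_probs(logits)  # (S, ..., K, K)
        for s in range(S):
            p = perms[s]
            probs[s] = probs[s][..., p, :][..., :, p]
        return probs_to_logits(probs)

    def permute_states(logits):
        probs = logits_to_probs(logits)  # (S, ..., K, J, C)
        for s in range(S):
            probs[s] = np.take(probs[s], perms[s], axis=-3)
        return probs_to_logits(probs)

    out.group_trans_logits = permute_trans(fit.group_trans_logits)
    out.group_emis_logits = permute_states(fit.group_emis_logits)
    out.re_var_trans = np.take_along_axis(fit.re_var_trans, perms, axis=1)
    out.re_var_emis = np.take_along_axis(fit.re_var_emis, perms, axis=1)
    if fit.subject_trans_logits.size:
        out.subject_trans_logits = permute_trans(fit.subject_trans_logits)
    if fit.subject_emis_logits.size:
        out.subject_emis_logits = permute_states(fit.subject_emis_logits)
    out.state_labels = canonical_state_labels(fit.n_states)
    out.relabelled = True
    return out


def compute_aic(fit: MHMMFit) -> float:
    """AIC = −2·ℓ̂ + 2p with ℓ̂ the data log-likelihood at posterior-median
    group-level parameters applied to all subjects (states marginalised by
    the forward algorithm) and p the group-level parameter count
    K(K−1) + K·J·(C−1)."""
    gamma, theta = fit.posterior_median_group_params()
    K, J, C = fit.n_states, fit.n_symptoms, fit.n_levels
    ll = 0.0
    for i in range(fit.n_subjects):
        obs = fit.obs[i][fit.valid_week[i]]
        ll += forward_loglik(obs, gamma, theta)
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite log-likelihood at posterior-median parameters")
    p = K * (K - 1) + K * J * (C - 1)
    fit.aic = float(-2.0 * ll + 2.0 * p)
    return fit.aic


@dataclass
class ModelSelectionTable:
    """Per-K fit summary with the AIC-selected model marked."""

    table: pd.DataFrame
    selected_k: int
    fits: dict
    failures: dict = field(default_factory=dict)


def select_num_states(
    data: PanelDataset,
    k_range,
    priors: PriorSpec | None = None,
    mcmc: McmcConfig | None = None,
    keep_fits: bool = True,
) -> ModelSelectionTable:
    """Fit each candidate number of states and select the AIC minimiser.

    Per-K failures are recorded and selection proceeds over the successes.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be nonempty")
    rows, fits, failures = [], {}, {}
    for K in k_range:
        try:
            fit = fit_mhmm(data, K, priors, mcmc, store_subject_draws=keep_fits)
            fit = relabel_states(fit)
            aic = compute_aic(fit)
            p = K * (K - 1) + K * fit.n_symptoms * (fit.n_levels - 1)
            rows.append({"K": K, "aic": aic, "loglik": p - aic / 2.0, "n_parameters": p})
            if keep_fits:
                fits[K] = fit
        except Exception as exc:  # noqa: BLE001 - per-K failure is recorded
            logger.warning("fit with K=%d failed: %s", K, exc)
            failures[K] = str(exc)
    if not rows:
        raise RuntimeError("every candidate fit failed")
    table = pd.DataFrame(rows)
    table["selected"] = table["aic"] == table["aic"].min()
    selected = int(table.loc[table["selected"], "K"].iloc[0])
    return ModelSelectionTable(table=table, selected_k=selected, fits=fits, failures=failures)


def save_fit(fit: MHMMFit, basepath) -> None:
    """Serialise a fit to ``<basepath>.npz`` (arrays) plus a JSON manifest
    ``<basepath>.manifest.json`` describing dimensions, labels and settings."""
    import dataclasses
    import json
    from pathlib import Path

    basepath = Path(basepath)
    arrays = {
        "group_trans_logits": fit.group_trans_logits,
        "group_emis_logits": fit.group_emis_logits,
        "re_var_trans": fit.re_var_trans,
        "re_var_emis": fit.re_var_emis,
        "subject_trans_logits": fit.subject_trans_logits,
        "subject_emis_logits": fit.subject_emis_logits,
        "loglik_trace": fit.loglik_trace,
        "obs": fit.obs,
        "valid_week": fit.valid_week,
    }
    np.savez_compressed(basepath.with_suffix(".npz"), **arrays)
    manifest = {
        "n_states": fit.n_states,
        "n_symptoms": fit.n_symptoms,
        "n_levels": fit.n_levels,
        "subject_ids": list(map(str, fit.subject_ids)),
        "symptoms": fit.symptoms,
        "state_labels": fit.state_labels,
        "relabelled": fit.relabelled,
        "aic": fit.aic,
        "mcmc": dataclasses.asdict(fit.mcmc),
        "priors": dataclasses.asdict(fit.priors),
        "acceptance": {k: np.asarray(v).tolist() for k, v in fit.acceptance.items()},
    }
    basepath.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=2))


def load_fit(basepath) -> MHMMFit:
    """Inverse of :func:`save_fit`."""
    import json
    from pathlib import Path

    basepath = Path(basepath)
    man = json.loads(basepath.with_suffix(".manifest.json").read_text())
    arr = np.load(basepath.with_suffix(".npz"))
    fit = MHMMFit(
        n_states=man["n_states"],
        n_symptoms=man["n_symptoms"],
        n_levels=man["n_levels"],
        subject_ids=man["subject_ids"],
        symptoms=man["symptoms"],
        group_trans_logits=arr["group_trans_logits"],
        group_emis_logits=arr["group_emis_logits"],
        re_var_trans=arr["re_var_trans"],
        re_var_emis=arr["re_var_emis"],
        subject_trans_logits=arr["subject_trans_logits"],
        subject_emis_logits=arr["subject_emis_logits"],
        loglik_trace=arr["loglik_trace"],
        acceptance={k: np.asarray(v) for k, v in man["acceptance"].items()},
        mcmc=McmcConfig(**man["mcmc"]),
        priors=PriorSpec(**man["priors"]),
        obs=arr["obs"],
        valid_week=arr["valid_week"],
        state_labels=man["state_labels"],
        relabelled=man["relabelled"],
        aic=man["aic"],
    )
    return fit


def convergence_diagnostics(fit: MHMMFit) -> dict:
    """Trace-based diagnostics on the group-level logits.

    Split-chain scale reduction and effective sample size (via arviz) plus
    the post-burn-in acceptance-rate summary; thresholds are logged, not
    enforced.
    """
    import arviz as az

    S = fit.n_draws
    half = S // 2
    flags = []
    report = {}
    for name, arr in (("transition", fit.group_trans_logits),
                      ("emission", fit.group_emis_logits)):
        flat = arr.reshape(S, -1)
        if flat.shape[1] == 0:
            continue
        if np.any(flat.std(axis=0) == 0):
            flags.append(f"{name} group logits contain constant (stuck) traces")
            report[f"rhat_{name}"] = np.inf
            report[f"ess_{name}"] = 0.0
            continue
        split = flat[: 2 * half].reshape(2, half, -1)
        rhat = az.rhat(az.convert_to_dataset(split))["x"].values
        ess = az.ess(az.convert_to_dataset(split))["x"].values
        report[f"rhat_{name}"] = float(np.nanmax(rhat))
        report[f"ess_{name}"] = float(np.nanmin(ess))
        if report[f"rhat_{name}"] > 1.1:
            flags.append(f"max split-Rhat for {name} logits exceeds 1.1")
    for name in ("transition", "emission"):
        rates = np.atleast_1d(fit.acceptance[name])
        report[f"acceptance_{name}"] = rates
        if fit.n_states > 1 or name == "emission":
            low, high = 0.10, 0.60
            if np.any((rates < low) | (rates > high)):
                flags.append(f"{name} acceptance rates outside [{low}, {high}]")
    report["flags"] = flags
    for key, val in report.items():
        if key != "flags":
            logger.info("diagnostic %s = %s", key, val)
    return report
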