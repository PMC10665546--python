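"""Markov-chain dynamics of latent symptom states.

For each subject's transition matrix Γ this module computes the quantities
used to summarise state dynamics:

* inertia — the diagonal Γ_ii, the probability of remaining in state i
  across consecutive weeks;
* stationary distribution π — long-run occupancy, πΓ = π;
* mean first-passage times m_ij — expected number of weeks to first reach
  state j starting from state i (off-diagonal only);
* mean recurrence times r_i = 1/π_i — expected number of weeks for a chain
  in state i to return to i (ergodic-chain identity).

Group-level summaries are unweighted means across subjects of the
per-subject quantities.  Note that averaging nonlinear functionals across
subjects is not the same as evaluating them at the group-mean matrix: by
convexity of 1/π the mean of per-subject recurrence times is at least the
recurrence time of the mean matrix (Jensen).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hmm_core import viterbi_decode

logger = logging.getLogger(__name__)

__all__ = [
    "IrreducibilityError",
    "stationary_distribution",
    "mean_first_passage",
    "recurrence_time",
    "empirical_recurrence_time",
    "SubjectDynamics",
    "GroupDynamics",
    "summarize_dynamics",
    "decode_states",
    "emission_profile_table",
    "transition_report",
]


class IrreducibilityError(ValueError):
    """The chain is reducible (or periodic) and the quantity is undefined."""


def _communicating_classes(gamma: np.ndarray, tol: float = 1e-12):
    """Strongly connected components of the positive-support digraph."""
    K = gamma.shape[0]
    adj = gamma > tol
    reach = adj | np.eye(K, dtype=bool)
    for _ in range(int(np.ceil(np.log2(max(K, 2))))):
        reach = reach | (reach @ reach)
    mutual = reach & reach.T
    seen, classes = set(), []
    for i in range(K):
        if i in seen:
            continue
        cls = tuple(np.flatnonzero(mutual[i]))
        classes.append(cls)
        seen.update(cls)
    return classes


def _check_irreducible(gamma: np.ndarray) -> None:
    classes = _communicating_classes(gamma)
    if len(classes) > 1:
        blocks = ", ".join(str(list(c)) for c in classes)
        raise IrreducibilityError(
            f"transition matrix is reducible; communicating classes: {blocks}"
        )


def _period(gamma: np.ndarray, tol: float = 1e-12) -> int:
    """Period of an irreducible chain via gcd of return-cycle lengths."""
    import math

    K = gamma.shape[0]
    adj = gamma > tol
    # BFS levels from state 0; gcd of (level[u] + 1 - level[v]) over edges u→v
    level = np.full(K, -1)
    level[0] = 0
    frontier = [0]
    while frontier:
        nxt = []
        for u in frontier:
            for v in np.flatnonzero(adj[u]):
                if level[v] < 0:
                    level[v] = level[u] + 1
                    nxt.append(v)
        frontier = nxt
    g = 0
    for u in range(K):
        for v in np.flatnonzero(adj[u]):
            g = math.gcd(g, level[u] + 1 - level[v])
    return abs(g) if g else 1


def stationary_distribution(gamma: np.ndarray, *, require_aperiodic: bool = True) -> np.ndarray:
    """Stationary distribution π solving πΓ = π, Σπ = 1 (linear system).

    Raises :class:`IrreducibilityError` for reducible chains (naming the
    communicating classes) and, when ``require_aperiodic``, for periodic ones.
    """
    gamma = np.asarray(gamma, dtype=float)
    _check_irreducible(gamma)
    if require_aperiodic:
        d = _period(gamma)
        if d > 1:
            raise IrreducibilityError(f"chain is periodic with period {d}")
    K = gamma.shape[0]
    A = gamma.T - np.eye(K)
    A[-1] = 1.0  # replace one balance equation with the normalisation
    b = np.zeros(K)
    b[-1] = 1.0
    pi = np.linalg.solve(A, b)
    return pi


def mean_first_passage(gamma: np.ndarray) -> np.ndarray:
    """Mean first-passage time matrix m (weeks); m_ij for i≠j, NaN diagonal.

    For each target state j the off-diagonal column solves the linear system
    m_ij = 1 + Σ_{k≠j} Γ_ik m_kj.
    """
    gamma = np.asarray(gamma, dtype=float)
    _check_irreducible(gamma)
    K = gamma.shape[0]
    m = np.full((K, K), np.nan)
    for j in range(K):
        idx = [i for i in range(K) if i != j]
        A = np.eye(K - 1) - gamma[np.ix_(idx, idx)]
        try:
            sol = np.linalg.solve(A, np.ones(K - 1))
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise IrreducibilityError(f"singular passage system for target {j}") from exc
        for i, mi in zip(idx, sol):
            m[i, j] = mi
    return m


def recurrence_time(gamma: np.ndarray) -> np.ndarray:
    """Mean recurrence time r_i = 1/π_i of an ergodic chain (weeks)."""
    pi = stationary_distribution(gamma)
    return 1.0 / pi


def empirical_recurrence_time(path: np.ndarray, n_states: int) -> np.ndarray:
    """Decoded-path alternative: mean observed return time per state (NaN if
    a state never recurs in the path)."""
    path = np.asarray(path)
    out = np.full(n_states, np.nan)
    for k in range(n_states):
        idx = np.flatnonzero(path == k)
        if idx.size >= 2:
            out[k] = float(np.diff(idx).mean())
    return out


@dataclass
class SubjectDynamics:
    """Per-subject Markov dynamics derived from the posterior-mean matrix."""

    subject_id: object
    gamma: np.ndarray
    inertia: np.ndarray
    stationary: np.ndarray | None
    first_passage: np.ndarray | None
    recurrence: np.ndarray | None
    occupancy: np.ndarray


@dataclass
class GroupDynamics:
    """Unweighted across-subject means of the per-subject quantities."""

    state_labels: list[str]
    gamma: np.ndarray
    inertia: np.ndarray
    stationary: np.ndarray
    first_passage: np.ndarray
    recurrence: np.ndarray
    occupancy: np.ndarray
    n_subjects: int
    n_excluded: int = 0
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def _subject_dynamics(subject_id, gamma, occupancy) -> SubjectDynamics:
    try:
        pi = stationary_distribution(gamma)
        fp = mean_first_passage(gamma)
        rec = 1.0 / pi
    except IrreducibilityError:
        logger.warning(
            "subject %s has a reducible/periodic posterior-mean matrix; "
            "excluded from passage/recurrence averages",
            subject_id,
        )
        pi = fp = rec = None
    return SubjectDynamics(
        subject_id=subject_id,
        gamma=gamma,
        inertia=np.diag(gamma).copy(),
        stationary=pi,
        first_passage=fp,
        recurrence=rec,
        occupancy=occupancy,
    )


def summarize_dynamics(fit) -> tuple[list[SubjectDynamics], GroupDynamics]:
    """Per-subject and group-average dynamics from a fitted multilevel HMM.

    Per-subject quantities are computed from the posterior-mean subject
    transition matrices; occupancy comes from Viterbi decoding under the
    posterior-mean subject parameters.  Subjects whose posterior-mean matrix
    is reducible are excluded from the passage/recurrence averages with a
    logged warning.
    """
    K = fit.n_states
    subj_gammas = fit.subject_transition_means()
    subj_thetas = fit.subject_emission_means()
    per_subject: list[SubjectDynamics] = []
    for i, sid in enumerate(fit.subject_ids):
        obs, weeks = fit.subject_observations(sid)
        path, _ = viterbi_decode(obs, subj_gammas[i], subj_thetas[i], weeks=weeks)
        occ = np.bincount(path, minlength=K) / path.size
        per_subject.append(_subject_dynamics(sid, subj_gammas[i], occ))
    ok = [d for d in per_subject if d.stationary is not None]
    group = GroupDynamics(
        state_labels=list(fit.state_labels),
        gamma=np.mean([d.gamma for d in per_subject], axis=0),
        inertia=np.mean([d.inertia for d in per_subject], axis=0),
        stationary=np.mean([d.stationary for d in ok], axis=0),
        first_passage=np.mean([d.first_passage for d in ok], axis=0),
        recurrence=np.mean([d.recurrence for d in ok], axis=0),
        occupancy=np.mean([d.occupancy for d in per_subject], axis=0),
        n_subjects=len(per_subject),
        n_excluded=len(per_subject) - len(ok),
    )
    return per_subject, group


def decode_states(fit) -> pd.DataFrame:
    """Viterbi-decoded state per observed subject-week, with canonical labels.

    Returns a long table (subject_id, week, state_index, state_label) used
    as the concurrent-state predictor layer of the comorbidity models.
    """
    subj_gammas = fit.subject_transition_means()
    subj_thetas = fit.subject_emission_means()
    frames = []
    for i, sid in enumerate(fit.subject_ids):
        obs, weeks = fit.subject_observations(sid)
        path, _ = viterbi_decode(obs, subj_gammas[i], subj_thetas[i], weeks=weeks)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "week": weeks,
                    "state_index": path,
                    "state_label": [fit.state_labels[k] for k in path],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def emission_profile_table(theta: np.ndarray, state_labels, symptom_names) -> pd.DataFrame:
    """Probability of endorsing each symptom at the subclinical-or-clinical
    level per state: P(rating ≥ subclinical | state) = 1 − P(absent | state)."""
    endorse = 1.0 - np.asarray(theta)[:, :, 0]
    return pd.DataFrame(endorse.T, index=list(symptom_names), columns=list(state_labels))


def transition_report(group: GroupDynamics) -> pd.DataFrame:
    """Transition-matrix report: group-average probabilities with inertias on
    the diagonal, labelled by canonical state names."""
    return pd.DataFrame(group.gamma, index=group.state_labels, columns=group.state_labels)
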