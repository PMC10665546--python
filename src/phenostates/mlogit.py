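"""Baseline-category multinomial-logit parameterisation of probability rows.

A probability row p = (p_1, ..., p_C) is represented by the C−1 log-odds
η_c = log(p_c / p_1), c = 2..C, with the first category as baseline.  This
maps row-stochastic constraints onto an unconstrained real vector, which is
what lets normal random effects act on transition and emission rows.
"""

from __future__ import annotations

import numpy as np

__all__ = ["probs_to_logits", "logits_to_probs"]


def probs_to_logits(p: np.ndarray) -> np.ndarray:
    """Log-odds relative to the first category; last axis shrinks by one."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore"):
        return np.log(p[..., 1:]) - np.log(p[..., :1])


def logits_to_probs(eta: np.ndarray) -> np.ndarray:
    """Inverse map (softmax with an implicit 0 logit for the baseline).

    Infinite logits (from degenerate probability rows) are handled: a +inf
    logit takes all mass in its row.
    """
    eta = np.asarray(eta, dtype=float)
    full = np.concatenate([np.zeros(eta.shape[:-1] + (1,)), eta], axis=-1)
    with np.errstate(invalid="ignore"):
        full = full - full.max(axis=-1, keepdims=True)
    np.nan_to_num(full, copy=False, nan=0.0)  # +inf − +inf: entries at the max
    ex = np.exp(full)
    return ex / ex.sum(axis=-1, keepdims=True)
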