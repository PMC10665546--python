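"""Optional matplotlib views of a fitted model.

Imported lazily so the core pipeline has no plotting dependency; install
the ``plots`` extra to use these helpers.
"""

from __future__ import annotations

import numpy as np


def plot_emission_profiles(fit, ax=None):
    """Grouped bars of P(rating ≥ subclinical | state) per symptom."""
    import matplotlib.pyplot as plt

    theta = fit.group_emission_mean()
    endorse = 1.0 - theta[:, :, 0]  # (K, J)
    K, J = endorse.shape
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    width = 0.8 / K
    x = np.arange(J)
    for k, label in enumerate(fit.state_labels):
        ax.bar(x + (k - (K - 1) / 2) * width, endorse[k], width, label=label)
    ax.set_xticks(x)
    ax.set_xticklabels(fit.symptoms, rotation=45, ha="right")
    ax.set_ylabel("P(subclinical or clinical | state)")
    ax.set_ylim(0, 1)
    ax.legend(title="state")
    return ax


def plot_transition_matrix(group, ax=None):
    """Heat map of the group-average transition matrix (inertias on the
    diagonal)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(group.gamma, vmin=0, vmax=1, cmap="Blues")
    labels = group.state_labels
    ax.set_xticks(range(len(labels)), labels, rotation=45, ha="right")
    ax.set_yticks(range(len(labels)), labels)
    ax.set_xlabel("to state")
    ax.set_ylabel("from state")
    for i in range(len(labels)):
        for j in range(len(labels)):
            ax.text(j, i, f"{group.gamma[i, j]:.2f}", ha="center", va="center",
                    color="white" if group.gamma[i, j] > 0.5 else "black")
    plt.colorbar(im, ax=ax, label="probability")
    return ax
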