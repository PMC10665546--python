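"""Synthetic cohort generator for weekly ordinal symptom panels.

Emulates the study design the pipeline targets: N subjects observed over
90 consecutive weeks, 10 depression symptoms rated on a 3-point ordinal
scale, subject-level heterogeneity in both transition and emission
probabilities (normal random effects on multinomial logits), a sex effect
on the transitions out of the low state, MCAR missingness plus a small
fraction of subjects with >80% of weeks missing, and weekly comorbidity
severities (five disorders, coded 1–6) driven by the latent state with
subject random intercepts and lag-1 autocorrelated noise.

The generator returns the realised ground truth (per-subject parameters
and latent paths) so that recovery of the fitted model can be scored.

Randomness is drawn from a single seed through named substreams in a fixed
order (covariates, subject parameters, latent paths, emissions,
missingness, comorbidity), so adding a downstream stage never perturbs an
upstream one and all outputs are bit-identical given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dynamics import IrreducibilityError, stationary_distribution
from .io_tables import DISORDERS, SYMPTOMS, PanelDataset
from .mlogit import logits_to_probs, probs_to_logits

__all__ = [
    "ConfigurationError",
    "ComorbidityLink",
    "GeneratorConfig",
    "TrueParameters",
    "default_config",
    "simulate_dataset",
    "simulate_comorbidity",
    "inject_missingness",
    "STATE_NAMES",
]

#: Generator state order; canonical relabelling in the fit sorts by symptom
#: endorsement and therefore reports (low, cognitive_physical, elevated).
STATE_NAMES = ("low", "elevated", "cognitive_physical")

_SUBSTREAMS = ("covariates", "subject_params", "paths", "emissions", "missingness", "comorbidity")


class ConfigurationError(ValueError):
    """The generator configuration is internally inconsistent."""


@dataclass
class ComorbidityLink:
    """Linear link from the latent state to one disorder's weekly severity.

    severity*_t = intercept + coef_elevated·I(state=elevated)
    + coef_cogphys·I(state=cognitive_physical) + b_subject + e_t,
    with b ~ N(0, subject_intercept_sd²) and e a stationary AR(1) process
    with lag-1 correlation ``ar1_rho`` and innovation scale such that
    sd(e) = noise_sd.  Observed severity is the latent value rounded and
    clamped to 1..6.
    """

    intercept: float
    coef_elevated: float = 0.0
    coef_cogphys: float = 0.0
    subject_intercept_sd: float = 0.5
    ar1_rho: float = 0.5
    noise_sd: float = 0.6

    def validate(self, name: str) -> None:
        if not (-1.0 < self.ar1_rho < 1.0):
            raise ConfigurationError(f"{name}: ar1_rho must lie strictly inside (-1, 1)")
        if self.subject_intercept_sd < 0 or self.noise_sd < 0:
            raise ConfigurationError(f"{name}: scales must be nonnegative")


@dataclass
class GeneratorConfig:
    n_subjects: int = 120
    n_weeks: int = 90
    n_symptoms: int = 10
    n_levels: int = 3
    n_states: int = 3
    group_transition: np.ndarray | None = None
    group_emission: np.ndarray | None = None
    re_sd_transition: float = 0.4
    re_sd_emission: float = 0.3
    female_transition_effects: dict = field(default_factory=dict)
    missing_rate: float = 0.003
    heavy_missing_subject_fraction: float = 0.0
    comorbidity_link: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_states < 1:
            raise ConfigurationError("n_states must be >= 1")
        if self.n_levels < 2:
            raise ConfigurationError("n_levels must be >= 2")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if not (0.0 <= self.heavy_missing_subject_fraction <= 1.0):
            raise ConfigurationError("heavy_missing_subject_fraction must be in [0, 1]")
        if self.re_sd_transition < 0 or self.re_sd_emission < 0:
            raise ConfigurationError("random-effect SDs must be nonnegative")
        K, J, C = self.n_states, self.n_symptoms, self.n_levels
        gt = np.asarray(self.group_transition, dtype=float)
        if gt.shape != (K, K):
            raise ConfigurationError(f"group_transition must be {K}x{K}")
        if (gt < 0).any() or not np.allclose(gt.sum(axis=1), 1.0, atol=1e-12):
            raise ConfigurationError("group_transition rows must be probabilities summing to 1")
        ge = np.asarray(self.group_emission, dtype=float)
        if ge.shape != (K, J, C):
            raise ConfigurationError(f"group_emission must be {K}x{J}x{C}")
        if (ge < 0).any() or not np.allclose(ge.sum(axis=2), 1.0, atol=1e-12):
            raise ConfigurationError("group_emission rows must be probabilities summing to 1")
        for (i, j), _ in self.female_transition_effects.items():
            if not (0 <= i < K) or not (0 <= j < K):
                raise ConfigurationError(f"female effect targets unknown transition ({i},{j})")
            if j == 0:
                raise ConfigurationError(
                    "female effects act on baseline-category logits; destination "
                    "state 0 is the baseline and cannot be shifted directly"
                )
        for name, link in self.comorbidity_link.items():
            link.validate(name)

    def substream(self, name: str) -> np.random.Generator:
        """Named child stream of the shared seed (fixed documented order)."""
        idx = _SUBSTREAMS.index(name)
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(len(_SUBSTREAMS))[idx])


@dataclass
class TrueParameters:
    """Realised ground truth for scoring parameter recovery."""

    subject_transition: np.ndarray  # (n, K, K)
    subject_emission: np.ndarray  # (n, K, J, C)
    latent_paths: np.ndarray  # (n, T), 0-based states
    covariates: pd.DataFrame
    group_transition: np.ndarray
    group_emission: np.ndarray
    state_names: tuple


def _default_group_transition() -> np.ndarray:
    # diagonals: low 0.887, elevated 0.865, cognitive-physical 0.870;
    # off-diagonal mass split equally within each row
    diag = np.array([0.887, 0.865, 0.870])
    gt = np.empty((3, 3))
    for i in range(3):
        gt[i] = (1.0 - diag[i]) / 2.0
        gt[i, i] = diag[i]
    return gt


def _default_group_emission() -> np.ndarray:
    # Invented per-symptom (absent, subclinical, clinical) profiles
    # reproducing the qualitative pattern of the three states: the low state
    # rarely endorses anything; the elevated state endorses every symptom;
    # the cognitive-physical state matches the elevated state on
    # worthlessness/guilt, psychomotor, appetite/weight and sleep, matches
    # the low state on irritable mood and fatigue, and is intermediate
    # elsewhere.
    low = np.tile([0.90, 0.08, 0.02], (len(SYMPTOMS), 1))
    elevated = np.tile([0.15, 0.45, 0.40], (len(SYMPTOMS), 1))
    cogphys = np.tile([0.55, 0.30, 0.15], (len(SYMPTOMS), 1))
    high_in_cogphys = ["worthlessness_guilt", "psychomotor", "appetite_weight", "sleep_problems"]
    low_in_cogphys = ["irritable_mood", "fatigue"]
    for s in high_in_cogphys:
        cogphys[SYMPTOMS.index(s)] = [0.20, 0.50, 0.30]
    for s in low_in_cogphys:
        cogphys[SYMPTOMS.index(s)] = [0.88, 0.10, 0.02]
    return np.stack([low, elevated, cogphys])


def _default_comorbidity_links() -> dict:
    # Modest state effects mirroring the sign pattern of the reported
    # comorbidity associations (externalizing up in the elevated state for
    # ODD, down for CD; weak/near-null links for the anxiety disorders).
    return {
        "ADHD": ComorbidityLink(intercept=2.2, coef_elevated=0.0, coef_cogphys=0.0,
                                subject_intercept_sd=0.8),
        "CD": ComorbidityLink(intercept=1.8, coef_elevated=-0.3, coef_cogphys=-0.3,
                              subject_intercept_sd=0.6),
        "ODD": ComorbidityLink(intercept=2.0, coef_elevated=0.5, coef_cogphys=-0.3,
                               subject_intercept_sd=0.7),
        "GAD": ComorbidityLink(intercept=2.0, coef_elevated=-0.2, coef_cogphys=-0.2,
                               subject_intercept_sd=0.6),
        "SAD": ComorbidityLink(intercept=1.5, coef_elevated=0.0, coef_cogphys=-0.1,
                               subject_intercept_sd=0.4, noise_sd=0.5),
    }


def default_config(**overrides) -> GeneratorConfig:
    """Study-mirroring default configuration.

    120 subjects × 90 weeks × 10 symptoms, three states in generator order
    (low, elevated, cognitive-physical) with self-transition probabilities
    0.887 / 0.865 / 0.870, random-effect SD 0.4 on transition logits and
    0.3 on emission logits, a +0.3 logit sex effect on the two transitions
    out of the low state (≈ +0.02 on the probability scale), cell-level
    MCAR missingness of 0.003 (≈3% of subject-weeks lose at least one
    rating), and five linked comorbidity series.
    """
    cfg = GeneratorConfig(
        group_transition=_default_group_transition(),
        group_emission=_default_group_emission(),
        female_transition_effects={(0, 1): 0.3, (0, 2): 0.3},
        comorbidity_link=_default_comorbidity_links(),
        heavy_missing_subject_fraction=1.0 / 30.0,
    )
    cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


def _draw_covariates(config: GeneratorConfig) -> pd.DataFrame:
    rng = config.substream("covariates")
    n = config.n_subjects
    female = rng.binomial(1, 0.533, size=n)
    age = np.clip(np.round(rng.normal(12.26, 2.35, size=n), 1), 7.0, 17.0)
    minority = rng.binomial(1, 0.317, size=n)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:03d}" for i in range(n)],
            "female": female,
            "age": age,
            "ethnoracial_minority": minority,
        }
    )


def _subject_parameters(config: GeneratorConfig, covariates: pd.DataFrame):
    rng = config.substream("subject_params")
    n, K = config.n_subjects, config.n_states
    J, C = config.n_symptoms, config.n_levels
    gt_logits = probs_to_logits(np.asarray(config.group_transition, dtype=float))
    ge_logits = probs_to_logits(np.asarray(config.group_emission, dtype=float))
    t_logits = gt_logits[None] + rng.normal(0.0, config.re_sd_transition, size=(n, K, K - 1))
    e_logits = ge_logits[None] + rng.normal(0.0, config.re_sd_emission, size=(n, K, J, C - 1))
    female = covariates["female"].to_numpy()
    for (i, j), shift in config.female_transition_effects.items():
        t_logits[female == 1, i, j - 1] += shift
    return logits_to_probs(t_logits), logits_to_probs(e_logits)


def _initial_distribution(gamma: np.ndarray) -> np.ndarray:
    """Subject initial state distribution: stationary distribution of the
    subject's matrix; uniform fallback when the matrix is reducible (every
    stationary distribution of e.g. the identity matrix is valid)."""
    try:
        return stationary_distribution(gamma, require_aperiodic=False)
    except IrreducibilityError:
        return np.full(gamma.shape[0], 1.0 / gamma.shape[0])


def simulate_dataset(config: GeneratorConfig):
    """Simulate the panel, the covariates, and the realised truth.

    Returns ``(panel, covariates, truth)``.  Missingness is NOT applied
    here; pass the result through :func:`inject_missingness`.
    """
    config.validate()
    covariates = _draw_covariates(config)
    trans, emis = _subject_parameters(config, covariates)
    n, T, J = config.n_subjects, config.n_weeks, config.n_symptoms
    K = config.n_states

    rng_paths = config.substream("paths")
    paths = np.empty((n, T), dtype=np.int64)
    for i in range(n):
        init = _initial_distribution(trans[i])
        u = rng_paths.random(T)
        paths[i, 0] = np.searchsorted(np.cumsum(init), u[0], side="right")
        cum = np.cumsum(trans[i], axis=1)
        for t in range(1, T):
            paths[i, t] = np.searchsorted(cum[paths[i, t - 1]], u[t], side="right")
    paths = np.clip(paths, 0, K - 1)

    rng_emit = config.substream("emissions")
    u = rng_emit.random((n, T, J))
    cum_emis = np.cumsum(emis, axis=3)  # (n, K, J, C)
    state_cum = np.take_along_axis(cum_emis, paths[:, :, None, None], axis=1)  # (n, T, J, C)
    ratings = (u[..., None] > state_cum).sum(axis=3) + 1  # external 1-based coding

    symptoms = SYMPTOMS[:J] if J <= len(SYMPTOMS) else [f"symptom_{j + 1}" for j in range(J)]
    rows = pd.DataFrame(
        {
            "subject_id": np.repeat(covariates["subject_id"].to_numpy(), T),
            "week": np.tile(np.arange(1, T + 1), n),
        }
    )
    for j, s in enumerate(symptoms):
        rows[s] = ratings[:, :, j].ravel()
    panel = PanelDataset(rows, symptoms)
    truth = TrueParameters(
        subject_transition=trans,
        subject_emission=emis,
        latent_paths=paths,
        covariates=covariates,
        group_transition=np.asarray(config.group_transition, dtype=float),
        group_emission=np.asarray(config.group_emission, dtype=float),
        state_names=STATE_NAMES if K == 3 else tuple(f"state_{k + 1}" for k in range(K)),
    )
    return panel, covariates, truth


def inject_missingness(data: PanelDataset, config: GeneratorConfig) -> PanelDataset:
    """MCAR masking at ``missing_rate`` per rating cell, plus a configured
    fraction of subjects masked on >80% of their weeks (entire rows)."""
    config.validate()
    rng = config.substream("missingness")
    out = data.copy()
    df = out.df
    n_rows, J = len(df), len(out.symptoms)
    mask = rng.random((n_rows, J)) < config.missing_rate
    subjects = list(df["subject_id"].unique())
    n_heavy = int(round(config.heavy_missing_subject_fraction * len(subjects)))
    heavy = rng.choice(len(subjects), size=n_heavy, replace=False) if n_heavy else []
    for si in heavy:
        rows = np.flatnonzero((df["subject_id"] == subjects[si]).to_numpy())
        n_mask = int(np.ceil(0.85 * rows.size))  # strictly more than 80% of weeks
        chosen = rng.choice(rows, size=n_mask, replace=False)
        mask[chosen, :] = True
    values = df[out.symptoms].to_numpy(dtype=object)
    values[mask] = pd.NA
    for j, s in enumerate(out.symptoms):
        df[s] = pd.array(values[:, j], dtype="Int64")
    return PanelDataset(df, list(out.symptoms))


def simulate_comorbidity(truth: TrueParameters, config: GeneratorConfig,
                         return_latent: bool = False):
    """Weekly comorbidity severities driven by the latent state.

    Latent severity per disorder-week follows the linear link in
    :class:`ComorbidityLink`; the AR(1) noise is initialised from its
    stationary distribution.  Observed severity is rounded and clamped to
    the 1..6 coding; ``return_latent`` additionally returns the unrounded
    per-disorder latent series (for calibration checks).
    """
    config.validate()
    if not config.comorbidity_link:
        raise ConfigurationError("no comorbidity links configured")
    for d in DISORDERS:
        if d not in config.comorbidity_link:
            raise ConfigurationError(f"missing comorbidity link specification for {d}")
    rng = config.substream("comorbidity")
    paths = truth.latent_paths
    n, T = paths.shape
    elevated = (paths == 1).astype(float)  # generator state order: low, elevated, cog-phys
    cogphys = (paths == 2).astype(float)
    frames = []
    latents = {}
    for d in DISORDERS:
        link = config.comorbidity_link[d]
        b = rng.normal(0.0, link.subject_intercept_sd, size=n)
        e = np.empty((n, T))
        rho, sd = link.ar1_rho, link.noise_sd
        e[:, 0] = rng.normal(0.0, sd, size=n)
        innov_sd = sd * np.sqrt(1.0 - rho**2)
        for t in range(1, T):
            e[:, t] = rho * e[:, t - 1] + rng.normal(0.0, innov_sd, size=n)
        latent = (
            link.intercept
            + link.coef_elevated * elevated
            + link.coef_cogphys * cogphys
            + b[:, None]
            + e
        )
        latents[d] = latent
        sev = np.clip(np.round(latent), 1, 6).astype(np.int64)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(truth.covariates["subject_id"].to_numpy(), T),
                    "week": np.tile(np.arange(1, T + 1), n),
                    "disorder": d,
                    "severity": sev.ravel(),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    if return_latent:
        return table, latents
    return table
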