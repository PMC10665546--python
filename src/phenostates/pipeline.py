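"""End-to-end pipeline: simulate → preprocess → fit → select → dynamics →
associate → report.

Each stage writes plain delimited-text artifacts into the output directory
and logs to stderr; the whole run is reproducible given the configuration
(including the seed).  The stages are also exposed individually through the
command-line interface (:mod:`phenostates.cli`).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_tables
from .association import fit_comorbidity_model, regress_transitions
from .dynamics import decode_states, emission_profile_table, summarize_dynamics, transition_report
from .multilevel import (
    McmcConfig,
    PriorSpec,
    compute_aic,
    convergence_diagnostics,
    fit_mhmm,
    relabel_states,
    save_fit,
    select_num_states,
)
from .synthetic_cohort import (
    ComorbidityLink,
    default_config,
    inject_missingness,
    simulate_comorbidity,
    simulate_dataset,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "build_generator_config", "build_mcmc_config"]


def build_generator_config(overrides: dict | None = None):
    """Generator config from a plain dict (e.g. parsed YAML)."""
    overrides = dict(overrides or {})
    if "comorbidity_link" in overrides:
        overrides["comorbidity_link"] = {
            k: ComorbidityLink(**v) for k, v in overrides["comorbidity_link"].items()
        }
    for key in ("group_transition", "group_emission"):
        if key in overrides:
            overrides[key] = np.asarray(overrides[key], dtype=float)
    if "female_transition_effects" in overrides:
        overrides["female_transition_effects"] = {
            tuple(int(x) for x in str(k).split("-")): float(v)
            for k, v in overrides["female_transition_effects"].items()
        }
    return default_config(**overrides)


def build_mcmc_config(overrides: dict | None = None) -> McmcConfig:
    cfg = McmcConfig(**(overrides or {}))
    cfg.validate()
    return cfg


def run_pipeline(config: dict, outdir) -> dict:
    """Run every stage; returns a dict of in-memory artifacts.

    ``config`` keys (all optional): ``seed``, ``generator`` (overrides of
    the default generator configuration), ``mcmc``, ``priors``,
    ``n_states`` (default 3), ``k_range`` (state-number candidates; omit to
    skip selection).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    logger.info("stage simulate: generating synthetic cohort")
    gen = build_generator_config({"seed": seed, **config.get("generator", {})})
    panel, cov, truth = simulate_dataset(gen)
    panel = inject_missingness(panel, gen)
    com = simulate_comorbidity(truth, gen)
    io_tables.write_panel(panel, out / "panel.csv")
    io_tables.write_covariates(cov, out / "covariates.csv")
    io_tables.write_comorbidity(com, out / "comorbidity.csv")
    np.savez_compressed(
        out / "truth.npz",
        subject_transition=truth.subject_transition,
        subject_emission=truth.subject_emission,
        latent_paths=truth.latent_paths,
    )

    logger.info("stage preprocess: applying exclusion rules")
    filtered, report = io_tables.apply_exclusions(panel)
    io_tables.write_panel(filtered, out / "panel_filtered.csv")
    (out / "exclusions.json").write_text(
        json.dumps(
            {
                "dropped_subjects": list(map(str, report.dropped_subjects)),
                "rows_before": report.rows_before,
                "rows_dropped_missing": report.rows_dropped_missing,
                "rows_after": report.rows_after,
            },
            indent=2,
        )
    )

    mcmc = build_mcmc_config({"seed": seed, **config.get("mcmc", {})})
    priors = PriorSpec(**config.get("priors", {}))
    n_states = int(config.get("n_states", 3))

    selection = None
    if config.get("k_range"):
        logger.info("stage select: AIC over K in %s", config["k_range"])
        selection = select_num_states(filtered, config["k_range"], priors, mcmc,
                                      keep_fits=False)
        selection.table.to_csv(out / "model_selection.csv", index=False)
        n_states = selection.selected_k
        logger.info("selected K = %d", n_states)

    logger.info("stage fit: K=%d multilevel HMM (%d iterations)", n_states, mcmc.n_iterations)
    fit = fit_mhmm(filtered, n_states, priors, mcmc)
    fit = relabel_states(fit)
    compute_aic(fit)
    diag = convergence_diagnostics(fit)
    save_fit(fit, out / "fit")

    logger.info("stage dynamics: per-subject and group Markov summaries")
    per_subject, group = summarize_dynamics(fit)
    transition_report(group).to_csv(out / "transition_report.csv")
    emission_profile_table(fit.group_emission_mean(), fit.state_labels,
                           fit.symptoms).to_csv(out / "emission_profile.csv")
    subj_rows = []
    for d in per_subject:
        row = {"subject_id": d.subject_id}
        for k, lab in enumerate(fit.state_labels):
            row[f"inertia_{lab}"] = d.inertia[k]
            row[f"occupancy_{lab}"] = d.occupancy[k]
            row[f"recurrence_{lab}"] = np.nan if d.recurrence is None else d.recurrence[k]
        subj_rows.append(row)
    pd.DataFrame(subj_rows).to_csv(out / "subject_dynamics.csv", index=False)
    group_rows = pd.DataFrame(
        {
            "state": group.state_labels,
            "inertia": group.inertia,
            "stationary": group.stationary,
            "recurrence_weeks": group.recurrence,
            "occupancy": group.occupancy,
        }
    )
    for j, lab in enumerate(group.state_labels):
        group_rows[f"first_passage_to_{lab}"] = group.first_passage[:, j]
    group_rows.to_csv(out / "group_dynamics.csv", index=False)

    logger.info("stage associate: demographic and comorbidity models")
    dyn_pairs = ([d.subject_id for d in per_subject],
                 np.stack([d.gamma for d in per_subject]))
    trans_reg = regress_transitions(dyn_pairs, cov)
    trans_reg.to_csv(out / "transition_regressions.csv", index=False)
    comorbid = None
    if fit.n_states == 3:
        decoded = decode_states(fit)
        comorbid = fit_comorbidity_model(com, decoded, dyn_pairs, cov)
        comorbid.to_frame().to_csv(out / "comorbidity_models.csv", index=False)
    else:
        logger.warning("comorbidity models require the three canonical states; skipped")

    logger.info("stage report: writing summary")
    _write_report(out, fit, group, selection, diag)
    return {
        "panel": filtered,
        "covariates": cov,
        "comorbidity": com,
        "fit": fit,
        "selection": selection,
        "per_subject": per_subject,
        "group": group,
        "transition_regressions": trans_reg,
        "comorbidity_models": comorbid,
        "diagnostics": diag,
    }


def _write_report(out: Path, fit, group, selection, diag) -> None:
    lines = ["phenostates pipeline report", "=" * 28, ""]
    if selection is not None:
        lines += ["State-number selection (AIC):",
                  selection.table.to_string(index=False), ""]
    lines += [f"Fitted states (K={fit.n_states}): {', '.join(fit.state_labels)}",
              f"AIC at posterior-median group parameters: {fit.aic:.2f}", "",
              "Group-average transition matrix (rows: from, cols: to):"]
    lines.append(pd.DataFrame(group.gamma, index=group.state_labels,
                              columns=group.state_labels).round(3).to_string())
    lines += ["", "Group-average dynamics per state:"]
    dyn = pd.DataFrame(
        {
            "inertia": group.inertia,
            "recurrence_weeks": group.recurrence,
            "occupancy": group.occupancy,
        },
        index=group.state_labels,
    ).round(3)
    lines.append(dyn.to_string())
    lines += ["", "Mean first-passage times (weeks, from row to column):"]
    lines.append(pd.DataFrame(group.first_passage, index=group.state_labels,
                              columns=group.state_labels).round(1).to_string())
    if diag.get("flags"):
        lines += ["", "Convergence flags:"] + [f"  - {f}" for f in diag["flags"]]
    (out / "report.txt").write_text("\n".join(lines) + "\n")
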