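"""Study-shaped tables: panel ratings, covariates, comorbidity series.

All tables are plain comma-separated text with missing cells as empty
fields.  Ratings use the external 3-point ordinal coding (1 = absent,
2 = subclinical, 3 = clinical) and are stored internally as pandas
nullable integers; the inference code receives 0-based category indices
with −1 for missing (see :mod:`phenostates.hmm_core`).

Preprocessing implements the cohort's exclusion rules: subjects with more
than 80% of study weeks missing are dropped, then any remaining
subject-week with a missing rating is removed.  Week indices are 1-based
and the gaps created by row removal are retained as index gaps for the
likelihood to bridge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SYMPTOMS = [
    "anhedonia",
    "depressed_mood",
    "irritable_mood",
    "sleep_problems",
    "fatigue",
    "appetite_weight",
    "concentration",
    "psychomotor",
    "worthlessness_guilt",
    "death_thoughts",
]

DISORDERS = ["ADHD", "CD", "ODD", "GAD", "SAD"]

RATING_LEVELS = (1, 2, 3)  # absent, subclinical, clinical
SEVERITY_LEVELS = tuple(range(1, 7))

__all__ = [
    "SYMPTOMS",
    "DISORDERS",
    "RATING_LEVELS",
    "SEVERITY_LEVELS",
    "SchemaError",
    "PanelDataset",
    "ExclusionReport",
    "combine_informant_reports",
    "apply_exclusions",
    "read_panel",
    "write_panel",
    "read_covariates",
    "write_covariates",
    "read_comorbidity",
    "write_comorbidity",
]


class SchemaError(ValueError):
    """A table violated its schema; the message names the offending cells."""


def _is_missing(x) -> bool:
    return x is None or x is pd.NA or (isinstance(x, float) and np.isnan(x))


def combine_informant_reports(parent, child, override: str = "none"):
    """Combine parent and child ratings of one symptom-week.

    The default ``override='none'`` applies the "or" rule: the combined
    rating is the elementwise maximum severity, so a symptom is marked
    present if either informant endorses it.  When the interviewer judges
    one informant uninformed for the period, ``override`` names the
    privileged informant and that informant's rating is taken.  A rating
    missing on one side falls back to the other side; both missing yields
    a missing combined rating.
    """
    if override not in {"none", "parent", "child"}:
        raise ValueError(f"unknown override {override!r}")

    def one(p, c):
        for v in (p, c):
            if not _is_missing(v) and v not in RATING_LEVELS:
                raise ValueError(f"rating {v!r} not in {RATING_LEVELS}")
        if override == "parent" and not _is_missing(p):
            return p
        if override == "child" and not _is_missing(c):
            return c
        if _is_missing(p):
            return c if not _is_missing(c) else pd.NA
        if _is_missing(c):
            return p
        return max(p, c)

    if np.ndim(parent) == 0 and np.ndim(child) == 0:
        return one(parent, child)
    parent = pd.array(np.asarray(parent, dtype=object).ravel(), dtype="Int64")
    child = pd.array(np.asarray(child, dtype=object).ravel(), dtype="Int64")
    return pd.array([one(p, c) for p, c in zip(parent, child)], dtype="Int64")


@dataclass
class PanelDataset:
    """Long-format subject-week symptom ratings.

    One row per subject-week; columns ``subject_id``, ``week`` (1-based,
    strictly increasing within subject) and one nullable-integer column per
    symptom with values in {1, 2, 3}.
    """

    df: pd.DataFrame
    symptoms: list[str] = field(default_factory=lambda: list(SYMPTOMS))

    def __post_init__(self) -> None:
        required = ["subject_id", "week", *self.symptoms]
        missing_cols = [c for c in required if c not in self.df.columns]
        if missing_cols:
            raise SchemaError(f"panel is missing columns {missing_cols}")
        self.df = self.df[required].copy()
        self.df["week"] = self.df["week"].astype(np.int64)
        for s in self.symptoms:
            self.df[s] = self.df[s].astype("Int64")
        self.validate()

    def validate(self) -> None:
        if self.df["subject_id"].nunique() < 1:
            raise SchemaError("panel must contain at least one subject")
        if (self.df["week"] < 1).any():
            raise SchemaError("weeks must be positive 1-based indices")
        for sid, grp in self.df.groupby("subject_id", sort=False):
            if not grp["week"].is_monotonic_increasing or grp["week"].duplicated().any():
                raise SchemaError(f"weeks not strictly increasing for subject {sid!r}")
        for s in self.symptoms:
            col = self.df[s]
            bad = col.notna() & ~col.isin(RATING_LEVELS)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise SchemaError(
                    f"row {row}, column {s!r}: invalid rating "
                    f"{self.df[s].iloc[row]} (allowed: {RATING_LEVELS} or empty)"
                )

    @property
    def subject_ids(self) -> list:
        return list(self.df["subject_id"].unique())

    @property
    def n_rows(self) -> int:
        return len(self.df)

    def subject_obs(self, subject_id) -> tuple[np.ndarray, np.ndarray]:
        """0-based observation matrix (T, J) with −1 for missing, plus weeks."""
        grp = self.df[self.df["subject_id"] == subject_id]
        obs = grp[self.symptoms].to_numpy(dtype=float)
        out = np.where(np.isnan(obs), -1, obs - 1).astype(np.int64)
        return out, grp["week"].to_numpy()

    def copy(self) -> "PanelDataset":
        return PanelDataset(self.df.copy(), list(self.symptoms))


@dataclass
class ExclusionReport:
    """What the preprocessing filter removed and why."""

    dropped_subjects: list
    subject_missing_fraction: dict
    rows_before: int
    rows_dropped_missing: int
    rows_after: int

    @property
    def empty(self) -> bool:
        return not self.dropped_subjects and self.rows_dropped_missing == 0


def apply_exclusions(
    data: PanelDataset, subject_missing_threshold: float = 0.8
) -> tuple[PanelDataset, ExclusionReport]:
    """Apply the cohort's missing-data exclusion rules.

    A subject-week counts as missing if its row is absent from the table or
    any of its ratings is missing; the denominator is the study span (the
    maximum week observed in the dataset).  Subjects whose missing fraction
    strictly exceeds ``subject_missing_threshold`` are dropped, then every
    remaining row with any missing rating is removed.  Filtering is
    idempotent.
    """
    if not (0.0 < subject_missing_threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    df = data.df
    span = int(df["week"].max())
    any_missing = df[data.symptoms].isna().any(axis=1)
    frac: dict = {}
    dropped = []
    for sid, grp in df.groupby("subject_id", sort=False):
        n_complete = int((~any_missing.loc[grp.index]).sum())
        f = 1.0 - n_complete / span
        frac[sid] = f
        if f > subject_missing_threshold:
            dropped.append(sid)
    keep = ~df["subject_id"].isin(dropped)
    kept = df[keep]
    kept_complete = kept[~any_missing.loc[kept.index]]
    report = ExclusionReport(
        dropped_subjects=dropped,
        subject_missing_fraction=frac,
        rows_before=len(df),
        rows_dropped_missing=int(len(kept) - len(kept_complete)),
        rows_after=len(kept_complete),
    )
    if len(kept_complete) == 0:
        raise ValueError(
            "exclusion filter removed every row; thresholds are over-aggressive "
            "for this dataset"
        )
    return PanelDataset(kept_complete.reset_index(drop=True), list(data.symptoms)), report


# ---------------------------------------------------------------------------
# plain-text readers/writers (comma-separated; missing cells empty)


def write_panel(data: PanelDataset, path) -> None:
    data.df.to_csv(path, index=False)


def read_panel(path, symptoms: list[str] | None = None) -> PanelDataset:
    df = pd.read_csv(path, dtype={"subject_id": str})
    symptoms = symptoms or [c for c in df.columns if c not in ("subject_id", "week")]
    for s in symptoms:
        col = pd.to_numeric(df[s], errors="coerce")
        raw_bad = df[s].notna() & col.isna()
        if raw_bad.any():
            row = int(np.flatnonzero(raw_bad.to_numpy())[0])
            raise SchemaError(f"row {row}, column {s!r}: non-numeric rating {df[s].iloc[row]!r}")
        df[s] = col.astype("Int64")
    return PanelDataset(df, symptoms)


def write_covariates(cov: pd.DataFrame, path) -> None:
    cov.to_csv(path, index=False)


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "female", "age", "ethnoracial_minority"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"covariate table missing columns {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        row = int(np.flatnonzero(df["subject_id"].duplicated().to_numpy())[0])
        raise SchemaError(f"row {row}: duplicate subject_id {df['subject_id'].iloc[row]!r}")
    for col, allowed in (("female", {0, 1}), ("ethnoracial_minority", {0, 1})):
        bad = ~df[col].isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(f"row {row}, column {col!r}: value {df[col].iloc[row]!r} not in {allowed}")
    if (df["age"] <= 0).any():
        row = int(np.flatnonzero((df["age"] <= 0).to_numpy())[0])
        raise SchemaError(f"row {row}: age must be positive")
    return df


def write_comorbidity(com: pd.DataFrame, path) -> None:
    com.to_csv(path, index=False)


def read_comorbidity(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "week", "disorder", "severity"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"comorbidity table missing columns {sorted(missing)}")
    bad = ~df["disorder"].isin(DISORDERS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(f"row {row}: unknown disorder {df['disorder'].iloc[row]!r}")
    bad = ~df["severity"].isin(SEVERITY_LEVELS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"row {row}: severity {df['severity'].iloc[row]!r} outside 1..6"
        )
    return df
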