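"""Cleaning the per-dose log into a model-ready feature matrix.

The pipeline mirrors standard practice for retrospective ECG/dosing data:
rule-based quality control (implausible QTc, rhythm-discordant PR),
heart-rate correction of the QT interval by Fridericia's cube-root formula,
exclusion of patients with off-label dose increases, train-median /
train-mode imputation, one-hot encoding of categorical fields and min-max
rescaling to [0, 1].  All summary statistics used to impute and rescale are
computed on training-set rows only, and the train/test split is made at the
patient level so no patient's doses straddle the split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

QTC_IMPLAUSIBLE_MS = 600.0  # strictly above -> set missing

#: default per-dose feature set: dosing characteristics plus the patient
#: covariates replicated onto each dose row
DOSE_NUMERIC = ["dose_position", "heart_rate", "pr_ms", "qrs_ms", "qt_ms",
                "qtc_ms", "creatinine"]
PATIENT_NUMERIC = ["age", "bmi", "lvef", "potassium", "magnesium"]
BINARY_FEATURES = ["sinus_rhythm", "female", "af", "vt", "ppm", "icd", "htn",
                   "dm", "cad", "chf", "beta_blocker", "ccb"]
CATEGORICAL_FEATURES = ["dose_mcg"]
NUMERIC_FEATURES = DOSE_NUMERIC + PATIENT_NUMERIC


def fridericia_qtc(qt_ms, heart_rate):
    """Heart-rate-corrected QT interval, QTc = QT / RR^(1/3).

    ``qt_ms`` is in milliseconds and the RR interval in seconds is
    60 / heart_rate.  At 60 bpm (RR = 1 s) the correction is the identity.
    Accepts scalars or arrays; raises on non-positive input.
    """
    qt = np.asarray(qt_ms, dtype=float)
    hr = np.asarray(heart_rate, dtype=float)
    if np.any(qt <= 0) or np.any(hr <= 0):
        raise ValueError("qt_ms and heart_rate must be positive")
    out = qt / np.cbrt(60.0 / hr)
    return float(out) if out.ndim == 0 else out


def qc_flag(doses: pd.DataFrame) -> pd.DataFrame:
    """Rule-based quality control replacing implausible values by missing.

    QTc strictly above 600 ms is physiologically implausible in this
    setting and is blanked; a PR interval recorded on a non-sinus
    (atrial fibrillation/flutter) rhythm is discordant and likewise
    blanked.  Values exactly at the 600 ms boundary are retained.
    """
    out = doses.copy()
    out.loc[out["qtc_ms"] > QTC_IMPLAUSIBLE_MS, "qtc_ms"] = np.nan
    discordant = (out["sinus_rhythm"].astype(bool) == False) & out["pr_ms"].notna()  # noqa: E712
    out.loc[discordant, "pr_ms"] = np.nan
    return out


def exclude_dose_increases(
    patients: pd.DataFrame, doses: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Drop every patient whose dose sequence ever increases.

    Dose increases during loading are off-label, so such patients are
    removed entirely from both tables.  Returns the retained tables and a
    report ``{"excluded_patient_ids": [...], "n_excluded": int}``.
    """
    excluded: list[str] = []
    for pid, grp in doses.groupby("patient_id", sort=False):
        seq = grp.sort_values("dose_position")["dose_mcg"].to_numpy()
        if np.any(np.diff(seq) > 0):
            excluded.append(str(pid))
    keep_pat = ~patients["patient_id"].astype(str).isin(excluded)
    keep_dose = ~doses["patient_id"].astype(str).isin(excluded)
    report = {"excluded_patient_ids": sorted(excluded), "n_excluded": len(excluded)}
    return patients[keep_pat].copy(), doses[keep_dose].copy(), report


def label_adjustments(doses: pd.DataFrame) -> tuple[pd.Series, int, int]:
    """Per-dose boolean "the dose was adjusted down at this position".

    A dose at position t >= 2 is an adjustment iff its amount is strictly
    below the previous position's.  Position 1 counts as an opportunity
    with no adjustment, so the number of opportunities equals the total
    number of administered doses.
    """
    ordered = doses.sort_values(["patient_id", "dose_position"])
    prev = ordered.groupby("patient_id", sort=False)["dose_mcg"].shift(1)
    labels = (ordered["dose_mcg"] < prev).fillna(False)
    labels = labels.reindex(doses.index)
    return labels.astype(bool), int(labels.sum()), int(len(labels))


@dataclass(frozen=True)
class SplitSpec:
    """Patient-level train/test partition."""

    train_patient_ids: tuple[str, ...]
    test_patient_ids: tuple[str, ...]
    fraction: float
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_patient_ids) & set(self.test_patient_ids):
            raise ValueError("train and test patient sets overlap")


def split_patients(
    patients: pd.DataFrame, fraction: float = 0.8, seed: int = 0
) -> SplitSpec:
    """Deterministic patient-level split with floor(fraction * n) in train."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    ids = sorted(patients["patient_id"].astype(str))
    if len(ids) < 2:
        raise ValueError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = math.floor(fraction * len(ids))
    train = tuple(sorted(ids[i] for i in perm[:n_train]))
    test = tuple(sorted(ids[i] for i in perm[n_train:]))
    return SplitSpec(train, test, fraction, seed)


@dataclass
class FeatureStats:
    """Imputation and rescaling statistics computed from training rows only."""

    medians: dict[str, float] = field(default_factory=dict)
    modes: dict[str, object] = field(default_factory=dict)
    minima: dict[str, float] = field(default_factory=dict)
    maxima: dict[str, float] = field(default_factory=dict)
    categories: dict[str, list] = field(default_factory=dict)


@dataclass
class FeatureMatrix:
    """Encoded per-dose design matrix with column provenance.

    ``provenance`` maps each output column to ``(source field, encoding)``
    where encoding is ``minmax`` or ``onehot``.
    """

    values: pd.DataFrame
    provenance: dict[str, tuple[str, str]]


def build_feature_table(patients: pd.DataFrame, doses: pd.DataFrame) -> pd.DataFrame:
    """Join patient covariates onto dose rows (the clustering feature set)."""
    pat_cols = ["patient_id"] + PATIENT_NUMERIC + [
        c for c in BINARY_FEATURES if c in patients.columns
    ]
    merged = doses.merge(patients[pat_cols], on="patient_id", how="left",
                         suffixes=("", "_pat"))
    cols = (["patient_id"] + CATEGORICAL_FEATURES + NUMERIC_FEATURES
            + BINARY_FEATURES)
    return merged[[c for c in cols if c in merged.columns]]


def compute_feature_stats(
    train: pd.DataFrame,
    numeric: list[str] | None = None,
    categorical: list[str] | None = None,
) -> FeatureStats:
    """Medians, modes, minima/maxima and category levels from training rows."""
    numeric = NUMERIC_FEATURES if numeric is None else numeric
    categorical = (CATEGORICAL_FEATURES + BINARY_FEATURES
                   if categorical is None else categorical)
    stats = FeatureStats()
    for col in numeric:
        if col not in train.columns:
            continue
        vals = train[col].dropna()
        if vals.empty:
            raise ValueError(f"column {col!r} entirely missing in training data")
        stats.medians[col] = float(vals.median())
        stats.minima[col] = float(vals.min())
        stats.maxima[col] = float(vals.max())
    for col in categorical:
        if col not in train.columns:
            continue
        vals = train[col].dropna()
        if vals.empty:
            raise ValueError(f"column {col!r} entirely missing in training data")
        stats.modes[col] = vals.mode(dropna=True).iloc[0]
        if col in CATEGORICAL_FEATURES:
            levels = sorted(vals.unique(), reverse=(col == "dose_mcg"))
            stats.categories[col] = list(levels)
    return stats


def impute(df: pd.DataFrame, stats: FeatureStats) -> pd.DataFrame:
    """Fill numeric missing with the training median, categorical with the
    training mode.  Leaves columns without stored statistics untouched."""
    out = df.copy()
    for col, med in stats.medians.items():
        if col in out.columns:
            out[col] = out[col].fillna(med)
    for col, mode in stats.modes.items():
        if col in out.columns:
            out[col] = out[col].fillna(mode).infer_objects(copy=False)
    return out


def encode_and_rescale(df: pd.DataFrame, stats: FeatureStats) -> FeatureMatrix:
    """One-hot encode categoricals and min-max rescale numerics to [0, 1].

    Rescaling uses the training min/max; out-of-range values (possible on
    test rows) are clipped to [0, 1] and a constant training column maps
    to 0.  Requires imputation to have been applied first.
    """
    cols: dict[str, np.ndarray] = {}
    provenance: dict[str, tuple[str, str]] = {}
    for col in stats.medians:
        if col not in df.columns:
            continue
        lo, hi = stats.minima[col], stats.maxima[col]
        vals = df[col].to_numpy(dtype=float)
        if hi > lo:
            scaled = np.clip((vals - lo) / (hi - lo), 0.0, 1.0)
        else:
            scaled = np.zeros_like(vals)
        cols[col] = scaled
        provenance[col] = (col, "minmax")
    for col, levels in stats.categories.items():
        if col not in df.columns:
            continue
        for lev in levels:
            name = f"{col}_{lev}"
            cols[name] = (df[col] == lev).to_numpy(dtype=float)
            provenance[name] = (col, "onehot")
    for col in stats.modes:
        if col in stats.categories or col not in df.columns:
            continue
        cols[col] = df[col].to_numpy(dtype=float)
        provenance[col] = (col, "minmax")
    values = pd.DataFrame(cols, index=df.index)
    if values.isna().any().any():
        missing = values.columns[values.isna().any()].tolist()
        raise ValueError(f"missing values remain after imputation: {missing}")
    return FeatureMatrix(values=values, provenance=provenance)


def preprocess_cohort(
    patients: pd.DataFrame,
    doses: pd.DataFrame,
    fraction: float = 0.8,
    seed: int = 0,
) -> dict:
    """Run the full cleaning pipeline and return its artifacts.

    Returns a dict with keys ``patients``, ``doses`` (QC'd, post-exclusion,
    with an ``adjustment`` column), ``features`` (FeatureMatrix aligned to
    the dose rows), ``split`` (SplitSpec), ``stats`` (train-only
    FeatureStats), ``exclusions`` (report dict), ``n_adjust`` and
    ``n_opportunities``.
    """
    doses = qc_flag(doses)
    missing_qt = doses["qt_ms"].notna() & doses["heart_rate"].notna() & doses["qtc_ms"].isna()
    if missing_qt.any():  # recover QTc from raw QT where the ECG allows
        doses.loc[missing_qt, "qtc_ms"] = fridericia_qtc(
            doses.loc[missing_qt, "qt_ms"], doses.loc[missing_qt, "heart_rate"]
        )
    patients, doses, exclusions = exclude_dose_increases(patients, doses)
    patients = patients.reset_index(drop=True)
    doses = doses.reset_index(drop=True)
    labels, n_adjust, n_opportunities = label_adjustments(doses)
    doses = doses.assign(adjustment=labels.astype(int))
    split = split_patients(patients, fraction=fraction, seed=seed)
    table = build_feature_table(patients, doses)
    train_rows = table["patient_id"].isin(split.train_patient_ids)
    stats = compute_feature_stats(table[train_rows])
    features = encode_and_rescale(impute(table, stats), stats)
    return {
        "patients": patients,
        "doses": doses,
        "features": features,
        "split": split,
        "stats": stats,
        "exclusions": exclusions,
        "n_adjust": n_adjust,
        "n_opportunities": n_opportunities,
    }
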