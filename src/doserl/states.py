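"""Unsupervised construction of discrete patient-dose states.

Each administered dose, described by the [0, 1] min-max-encoded feature
vector of patient and dosing characteristics, is mapped to one of k
discrete states by K-means.  Principal component analysis of the same
matrix and the within-cluster sum-of-squares (elbow) curve serve as
diagnostics for choosing k; the discrete states then index the rows of the
action-value table learned in :mod:`doserl.rl`.

Features enter clustering on the min-max scale rather than as z-scores, so
the encoding stage fully determines the geometry; K-means uses
k-means++-style seeding with a configurable number of restarts and keeps
the best fit by WSS.  State labels are arbitrary indices 0..k-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA


def pca_profile(features) -> tuple[np.ndarray, np.ndarray]:
    """Per-component and cumulative explained-variance fractions.

    Components are ordered by decreasing variance; the cumulative curve is
    non-decreasing and ends at 1.  Raises on fewer than 2 rows/columns or
    a constant matrix.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 rows and 2 columns")
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("constant feature matrix has no principal components")
    ratios = PCA().fit(X).explained_variance_ratio_
    return ratios, np.cumsum(ratios)


def components_for_threshold(ratios: np.ndarray, threshold: float = 0.90) -> int:
    """Smallest number of leading components whose cumulative explained
    variance reaches the threshold."""
    cumulative = np.cumsum(np.asarray(ratios, dtype=float))
    idx = np.searchsorted(cumulative, threshold - 1e-12)
    if idx >= len(cumulative):
        raise ValueError(f"threshold {threshold} not reached by any prefix")
    return int(idx) + 1


def wss_curve(
    features, k_values, seed: int = 0, n_restarts: int = 10
) -> dict[int, float]:
    """Within-cluster sum of squares of the best-of-restarts fit per k.

    WSS at k = 1 equals the total sum of squared deviations from the grand
    mean, and the curve is non-increasing in k.
    """
    X = np.asarray(features, dtype=float)
    out: dict[int, float] = {}
    for k in k_values:
        if not 1 <= k <= X.shape[0]:
            raise ValueError(f"k={k} outside 1..{X.shape[0]}")
        km = KMeans(n_clusters=int(k), n_init=n_restarts, random_state=seed)
        km.fit(X)
        out[int(k)] = float(km.inertia_)
    return out


@dataclass
class StateModel:
    """Fitted K-means state abstraction plus the PCA diagnostic profile."""

    k: int
    centroids: np.ndarray  # (k, n_features)
    columns: list[str]
    seed: int
    pca_variances: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape[0] != self.k:
            raise ValueError("centroid count must equal k")
        if len(np.unique(self.centroids, axis=0)) != self.k:
            raise ValueError("centroids must be distinct")
        pv = np.asarray(self.pca_variances, dtype=float)
        if pv.size and (pv.min() < 0 or pv.sum() > 1 + 1e-9):
            raise ValueError("invalid explained-variance fractions")


def fit_states(
    features: pd.DataFrame, k: int, seed: int = 0, n_restarts: int = 10
) -> StateModel:
    """Fit K-means on the encoded feature matrix (best of restarts by WSS)."""
    X = np.asarray(features, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    n_distinct = len(np.unique(X, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct rows")
    km = KMeans(n_clusters=int(k), n_init=n_restarts, random_state=seed)
    km.fit(X)
    pca = (pca_profile(X)[0] if min(X.shape) >= 2
           and not np.allclose(X.var(axis=0), 0) else np.array([]))
    columns = (list(features.columns) if isinstance(features, pd.DataFrame)
               else [f"f{i}" for i in range(X.shape[1])])
    return StateModel(k=int(k), centroids=km.cluster_centers_,
                      columns=columns, seed=seed, pca_variances=pca)


def assign_states(model: StateModel, features) -> np.ndarray:
    """Nearest-centroid (Euclidean) state id for every row."""
    X = np.asarray(features, dtype=float)
    if X.shape[1] != model.centroids.shape[1]:
        raise ValueError("feature dimension does not match the state model")
    d2 = ((X[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def profile_states(
    assignment: np.ndarray, dose_table: pd.DataFrame
) -> pd.DataFrame:
    """Per-state composition: size, dose-position and dose-amount
    distributions, and covariate means/percents on the raw scale.

    ``dose_table`` must be row-aligned with ``assignment`` and carry the
    raw (unencoded) columns; state sizes partition the doses.
    """
    assignment = np.asarray(assignment)
    if len(assignment) != len(dose_table):
        raise ValueError("assignment and dose table lengths differ")
    df = dose_table.copy()
    df["_state"] = assignment
    rows = []
    binary = [c for c in ["sinus_rhythm", "female", "beta_blocker", "ccb",
                          "chf", "cad", "htn", "dm", "ppm", "icd"]
              if c in df.columns]
    continuous = [c for c in ["age", "heart_rate", "qrs_ms", "qtc_ms",
                              "creatinine", "lvef"] if c in df.columns]
    for state, grp in df.groupby("_state", sort=True):
        row: dict = {"state": int(state), "n": len(grp)}
        pos = grp["dose_position"].value_counts(normalize=True).sort_index()
        row["dose_positions"] = ";".join(
            f"{int(p)}:{100 * f:.1f}%" for p, f in pos.items())
        amt = grp["dose_mcg"].value_counts(normalize=True).sort_index(ascending=False)
        row["dose_amounts"] = ";".join(
            f"{int(a)}mcg:{100 * f:.1f}%" for a, f in amt.items())
        for c in continuous:
            row[c] = float(grp[c].mean())
        for c in binary:
            row[c] = float(100 * grp[c].astype(float).mean())
        rows.append(row)
    return pd.DataFrame(rows)
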