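"""Descriptive statistics and supervised baselines.

Three kinds of analysis live here:

* group comparisons of baseline characteristics between successfully and
  unsuccessfully loaded patients (Pearson chi-square for categorical
  variables, pooled-variance t-test for continuous ones, with a Bonferroni
  note for the number of rows compared);
* univariate logistic associations with loading success, reported as odds
  ratios with Wald 95% confidence intervals, plus the p <= 0.05 screen;
* supervised classifiers of the dose-adjustment decision (L1 logistic
  regression, random forest, gradient-boosted trees, RBF-kernel SVM and
  k-nearest neighbours at k = 1 and k = 10), benchmarked against the naive
  always-"no adjustment" comparator that the heavy class imbalance makes
  hard to beat.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

#: patient-level variables compared between outcome groups, in report order
GROUP_COMPARISON_VARIABLES: list[tuple[str, str]] = [
    ("age", "continuous"),
    ("female", "categorical"),
    ("bmi", "continuous"),
    ("af", "categorical"),
    ("vt", "categorical"),
    ("ppm", "categorical"),
    ("icd", "categorical"),
    ("htn", "categorical"),
    ("dm", "categorical"),
    ("cad", "categorical"),
    ("chf", "categorical"),
    ("lvef", "continuous"),
    ("beta_blocker", "categorical"),
    ("ccb", "categorical"),
    ("potassium", "continuous"),
    ("magnesium", "continuous"),
    ("creatinine", "continuous"),
]


@dataclass
class GroupComparison:
    variable: str
    kind: str  # "categorical" | "continuous"
    test: str  # "chi-square" | "t-test"
    summary_pos: str  # success group
    summary_neg: str
    statistic: float
    p_value: float


@dataclass
class OddsResult:
    predictor: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    flag: Optional[str] = None  # "separation" | "degenerate" | None


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 table.

    Rows are groups, columns outcome: ``[[a, b], [c, d]]``.  Returns
    (statistic, p).  Equivalent to n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)).
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        raise ValueError("chi-square undefined: empty row or column margin")
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def pooled_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample pooled-variance (Student) t-test, ignoring missing."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    stat, p = sps.ttest_ind(x, y, equal_var=True)
    return float(stat), float(p)


def group_comparison_table(
    patients: pd.DataFrame,
    outcome: str = "success",
    variables: list[tuple[str, str]] | None = None,
) -> list[GroupComparison]:
    """Compare baseline characteristics between outcome groups."""
    variables = GROUP_COMPARISON_VARIABLES if variables is None else variables
    grp_pos = patients[patients[outcome].astype(bool)]
    grp_neg = patients[~patients[outcome].astype(bool)]
    if len(grp_pos) == 0 or len(grp_neg) == 0:
        raise ValueError("both outcome groups must be non-empty")
    rows: list[GroupComparison] = []
    for var, kind in variables:
        if var not in patients.columns:
            continue
        if kind == "categorical":
            a = int(grp_pos[var].astype(bool).sum())
            b = len(grp_pos) - a
            c = int(grp_neg[var].astype(bool).sum())
            d = len(grp_neg) - c
            if (a + c) == 0 or (b + d) == 0:  # constant variable
                stat, p = float("nan"), 1.0
            else:
                stat, p = chi_square_2x2(a, b, c, d)
            s_pos = f"{a} ({100 * a / len(grp_pos):.1f}%)"
            s_neg = f"{c} ({100 * c / len(grp_neg):.1f}%)"
            test = "chi-square"
        else:
            stat, p = pooled_t_test(grp_pos[var], grp_neg[var])
            s_pos = f"{grp_pos[var].mean():.1f} ± {grp_pos[var].std():.1f}"
            s_neg = f"{grp_neg[var].mean():.1f} ± {grp_neg[var].std():.1f}"
            test = "t-test"
        rows.append(GroupComparison(var, kind, test, s_pos, s_neg, stat, p))
    return rows


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Adjusted per-comparison significance level alpha / m."""
    if m < 1:
        raise ValueError(f"number of comparisons must be >= 1, got {m}")
    return alpha / m


def univariate_logistic(y, x, name: str = "x") -> OddsResult:
    """Maximum-likelihood univariate logistic fit of a binary outcome.

    Returns the odds ratio with its Wald 95% CI (computed on the log-odds
    scale and exponentiated).  A constant predictor or (quasi-)perfect
    separation yields a flagged result rather than an exception.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.unique(y[~np.isnan(y)]).size != 2:
        raise ValueError("outcome must be binary and non-degenerate")
    ok = ~(np.isnan(x) | np.isnan(y))
    y, x = y[ok], x[ok]
    if np.unique(x).size < 2:
        return OddsResult(name, float("nan"), float("nan"), float("nan"),
                          float("nan"), flag="degenerate")
    X = sm.add_constant(x)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        beta = fit.params[1]
        se = fit.bse[1]
        p = fit.pvalues[1]
    except Exception:
        return OddsResult(name, float("nan"), float("nan"), float("nan"),
                          float("nan"), flag="separation")
    if not np.isfinite(se) or se > 50 or abs(beta) > 50:
        return OddsResult(name, float(np.exp(beta)), float("nan"),
                          float("nan"), float("nan"), flag="separation")
    z = sps.norm.ppf(0.975)
    return OddsResult(name, float(np.exp(beta)), float(np.exp(beta - z * se)),
                      float(np.exp(beta + z * se)), float(p))


def stepwise_univariate_screen(
    y, candidates: pd.DataFrame, alpha: float = 0.05
) -> tuple[list[str], list[OddsResult]]:
    """Univariate screen: retain predictors with p <= alpha.

    Returns the retained predictor names and the full per-predictor report
    (flagged fits are reported but never retained).
    """
    results = [univariate_logistic(y, candidates[c], name=c)
               for c in candidates.columns]
    retained = [r.predictor for r in results
                if r.flag is None and r.p_value <= alpha]
    return retained, results


def regimen_patterns(
    patients: pd.DataFrame, doses: pd.DataFrame
) -> pd.DataFrame:
    """Tabulate the distinct dose regimens of successfully loaded patients.

    One row per unique ordered dose-amount sequence with its patient count,
    share among successful patients, and the total cardioversions after
    each position; a final ``unsuccessful`` row pools the failed patients.
    """
    succ_ids = set(patients.loc[patients["success"].astype(bool),
                                "patient_id"].astype(str))
    seqs: dict[tuple, dict] = {}
    n_succ = 0
    fail_row = {"n": 0, "cardioversions": []}
    for pid, grp in doses.groupby("patient_id", sort=False):
        grp = grp.sort_values("dose_position")
        key = tuple(int(d) for d in grp["dose_mcg"])
        cv = [int(c) for c in grp["cardioversions_after"]]
        if str(pid) in succ_ids:
            n_succ += 1
            cell = seqs.setdefault(key, {"n": 0, "cardioversions": [0] * len(key)})
            cell["n"] += 1
            for i, c in enumerate(cv):
                cell["cardioversions"][i] += c
        else:
            fail_row["n"] += 1
            fail_row["cardioversions"].append(sum(cv))
    rows = []
    for key, cell in sorted(seqs.items(), key=lambda kv: -kv[1]["n"]):
        rows.append({
            "pattern": "-".join(str(d) for d in key),
            "n": cell["n"],
            "share": cell["n"] / n_succ if n_succ else float("nan"),
            "cardioversions": ",".join(str(c) for c in cell["cardioversions"]),
        })
    rows.append({
        "pattern": "unsuccessful",
        "n": fail_row["n"],
        "share": float("nan"),
        "cardioversions": str(sum(fail_row["cardioversions"])),
    })
    return pd.DataFrame(rows, columns=["pattern", "n", "share", "cardioversions"])


def metrics_from_predictions(y_true, y_pred, y_score=None) -> MetricsReport:
    """Accuracy, precision, recall, F1 and AUC from hard predictions.

    precision = TP / (TP + FP) and recall = TP / (TP + FN), both 0 when
    their denominator is 0; F1 = 2 * precision * recall /
    (precision + recall), 0 when that denominator is 0.  AUC uses
    ``y_score`` when given, otherwise the hard predictions, and is 0.5
    when the truth is single-class.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    accuracy = float(np.mean(y_true == y_pred))
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) > 0 else 0.0)
    score = y_pred if y_score is None else np.asarray(y_score, dtype=float)
    if np.unique(y_true).size < 2 or np.unique(score).size < 2:
        auc = 0.5
    else:
        auc = float(roc_auc_score(y_true, score))
    return MetricsReport(accuracy, precision, recall, f1, auc)


def naive_classifier_metrics(labels) -> MetricsReport:
    """Metrics of the majority-class comparator that never predicts an
    adjustment: accuracy = 1 - positive rate, precision/recall/F1 = 0
    whenever any positive exists, AUC = 0.5."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("labels must be nonempty")
    return metrics_from_predictions(labels, np.zeros_like(labels))


def classifier_suite(seed: int = 0) -> dict[str, object]:
    """The five supervised model families (kNN at both k = 1 and k = 10).

    Hyperparameters beyond the stated ones are the library defaults.
    """
    return {
        "l1_logistic": LogisticRegression(l1_ratio=1, solver="liblinear",
                                          random_state=seed, max_iter=1000),
        "random_forest": RandomForestClassifier(random_state=seed),
        "boosted_tree": GradientBoostingClassifier(random_state=seed),
        "svm_rbf": SVC(kernel="rbf", random_state=seed),
        "knn_1": KNeighborsClassifier(n_neighbors=1),
        "knn_10": KNeighborsClassifier(n_neighbors=10),
    }


def fit_classifier_suite(X, y, seed: int = 0) -> dict[str, object]:
    """Fit every model family on the encoded training matrix."""
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training labels are single-class")
    models = classifier_suite(seed)
    for model in models.values():
        model.fit(np.asarray(X, dtype=float), y)
    return models


def evaluate_suite(models: dict[str, object], X, y) -> dict[str, MetricsReport]:
    """Evaluate fitted models on held-out doses."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    out = {}
    for name, model in models.items():
        pred = model.predict(X)
        if hasattr(model, "predict_proba"):
            score = model.predict_proba(X)[:, 1]
        else:
            score = model.decision_function(X)
        out[name] = metrics_from_predictions(y, pred, score)
    return out
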