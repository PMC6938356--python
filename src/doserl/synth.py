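"""Synthetic dose-loading cohorts with known ground truth.

The real study data (per-patient demographics and a per-dose log of 5-6
dofetilide administrations) are not publicly deposited, so every downstream
stage of the pipeline is exercised on synthetic cohorts whose marginal
distributions, dose-sequence shapes and covariate-outcome effect sizes are
configurable and known exactly.

The generator draws patient covariates independently from configured
marginals, simulates a non-increasing dose sequence of 5-6 doses with a
per-opportunity probability of lowering the dose (modulated by the running
QTc), and finally draws the binary loading-success outcome from a logistic
model whose *marginal* odds ratios are calibrated to the configured
targets.  Calibration matters because a conditional logistic coefficient is
attenuated when other covariates are marginalised out (non-collapsibility
of the odds ratio); solving for conditional coefficients that induce the
requested marginal odds ratios makes a univariate logistic refit an
unbiased check of the generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import root
from scipy.special import expit, logit

DOSE_LEVELS = (500, 250, 125)
ACTION_KEEP = "keep"
ACTION_LOWER = "lower"

#: Per-covariate marginal distributions of the emulated cohort:
#: ("normal", mean, sd) or ("bernoulli", p).  Units: age years, bmi kg/m2,
#: lvef percent, potassium mmol/L, magnesium mg/dL, creatinine mg/dL,
#: heart_rate bpm, ECG intervals ms.
DEFAULT_MARGINALS: dict[str, tuple] = {
    "age": ("normal", 66.7, 10.6),
    "female": ("bernoulli", 0.31),
    "bmi": ("normal", 30.1, 7.2),
    "af": ("bernoulli", 0.96),
    "vt": ("bernoulli", 0.034),
    "ppm": ("bernoulli", 0.065),
    "icd": ("bernoulli", 0.065),
    "htn": ("bernoulli", 0.45),
    "dm": ("bernoulli", 0.116),
    "cad": ("bernoulli", 0.21),
    "chf": ("bernoulli", 0.124),
    "lvef": ("normal", 54.3, 12.9),
    "beta_blocker": ("bernoulli", 0.576),
    "ccb": ("bernoulli", 0.237),
    "potassium": ("normal", 4.31, 0.46),
    "magnesium": ("normal", 2.0, 0.25),
    "creatinine": ("normal", 1.01, 0.25),
    "sinus_rhythm": ("bernoulli", 0.356),
    "heart_rate": ("normal", 81.5, 21.0),
    "pr_ms": ("normal", 180.6, 43.0),
    "qrs_ms": ("normal", 102.0, 25.7),
    "qtc_ms": ("normal", 445.9, 39.2),
}

#: Marginal odds-ratio targets of the success model (log scale).
DEFAULT_SUCCESS_LOG_ODDS: dict[str, float] = {
    "start_500": math.log(5.0),
    "sinus_rhythm": math.log(2.8),
    "any_adjustment": math.log(0.19),
    "cad": math.log(0.33),
}


class ConfigError(ValueError):
    """Raised for an invalid generator configuration."""


@dataclass(frozen=True)
class SynthConfig:
    """Ground-truth parameters of a synthetic loading cohort.

    Parameters
    ----------
    n_patients : int
        Cohort size; zero yields an empty cohort.
    seed : int
        Seed for all randomness in the generator.
    start_dose_probs : dict
        Probability of starting at 500 / 250 / 125 mcg; must sum to 1.
    base_adjust_prob : float
        Per-opportunity probability of lowering the dose when QTc is at or
        below ``adjust_qtc_threshold``.
    adjust_qtc_slope : float
        Log-odds increase of a dose-lowering per ms of QTc above the
        threshold.
    adjust_qtc_threshold : float
        QTc (ms) above which lowering becomes more likely.
    success_log_odds : dict
        Covariate name -> target marginal log odds ratio for loading
        success.  Recognised names: ``start_500``, ``sinus_rhythm``,
        ``any_adjustment``, ``cad``.
    success_rate : float
        Target marginal probability of successful loading.
    covariate_marginals : dict
        Per-covariate marginal distributions (see ``DEFAULT_MARGINALS``).
    missing_rate : float
        Probability that each maskable per-dose numeric value is missing.
    n_doses_range : (int, int)
        Inclusive range of doses administered per patient.
    qtc_drift_per_500 : float
        Mean QTc increase (ms) per 500 mcg dose administered.
    qtc_noise_sd : float
        SD of the per-dose Gaussian QTc innovation (ms).
    cardioversion_rate : float
        Poisson mean of electrical cardioversions after each dose.
    stop_after_adjustment : bool
        When True, a failed patient whose trajectory contains any lowering
        stops at the dose produced by the final adjustment: the remaining
        doses are never administered, so the last recorded dose is the
        decrease that preceded abandoning the load.  Failed trajectories
        may then be shorter than ``n_doses_range`` allows.
    """

    n_patients: int = 354
    seed: int = 0
    start_dose_probs: dict[int, float] = field(
        default_factory=lambda: {500: 0.72, 250: 0.26, 125: 0.02}
    )
    base_adjust_prob: float = 0.071
    adjust_qtc_slope: float = 0.02
    adjust_qtc_threshold: float = 500.0
    success_log_odds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUCCESS_LOG_ODDS)
    )
    success_rate: float = 0.871
    covariate_marginals: dict[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    missing_rate: float = 0.042
    n_doses_range: tuple[int, int] = (5, 6)
    stop_after_adjustment: bool = False
    qtc_drift_per_500: float = 8.0
    qtc_noise_sd: float = 10.0
    cardioversion_rate: float = 0.1

    def __post_init__(self) -> None:
        probs = self.start_dose_probs
        if set(probs) != set(DOSE_LEVELS):
            raise ConfigError(f"start_dose_probs must have keys {DOSE_LEVELS}")
        if any(not 0.0 <= p <= 1.0 for p in probs.values()):
            raise ConfigError("start_dose_probs entries must lie in [0, 1]")
        if abs(sum(probs.values()) - 1.0) > 1e-12:
            raise ConfigError("start_dose_probs must sum to 1")
        for name, value in [
            ("base_adjust_prob", self.base_adjust_prob),
            ("missing_rate", self.missing_rate),
            ("success_rate", self.success_rate),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        lo, hi = self.n_doses_range
        if not (1 <= lo <= hi):
            raise ConfigError(f"invalid n_doses_range {self.n_doses_range}")


@dataclass
class PatientRecord:
    """One enrolled subject: covariates, starting dose, loading outcome."""

    patient_id: str
    age: float
    female: bool
    bmi: float
    af: bool
    vt: bool
    ppm: bool
    icd: bool
    htn: bool
    dm: bool
    cad: bool
    chf: bool
    lvef: float
    beta_blocker: bool
    ccb: bool
    potassium: float
    magnesium: float
    creatinine: float
    start_dose: int
    success: bool


@dataclass
class DoseEvent:
    """One administered dose: pre-dose state and the decision taken after.

    ``action`` records what happened *after* this dose: ``lower`` iff the
    next administered dose is strictly smaller; the final dose of a
    trajectory is ``keep`` by convention (there is no subsequent dose).
    """

    patient_id: str
    dose_position: int
    dose_mcg: int
    sinus_rhythm: bool
    heart_rate: Optional[float]
    pr_ms: Optional[float]
    qrs_ms: Optional[float]
    qt_ms: Optional[float]
    qtc_ms: Optional[float]
    creatinine: Optional[float]
    cardioversions_after: int
    action: str


#: per-dose numeric fields that inject_missingness may blank
MASKABLE_FIELDS = ("heart_rate", "pr_ms", "qrs_ms", "qt_ms", "qtc_ms", "creatinine")

PATIENT_COLUMNS = [f.name for f in fields(PatientRecord)]
DOSE_COLUMNS = [f.name for f in fields(DoseEvent)]
_PATIENT_BOOL = ["female", "af", "vt", "ppm", "icd", "htn", "dm", "cad", "chf",
                 "beta_blocker", "ccb", "success"]


def _draw_covariates(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_patients
    cols: dict[str, np.ndarray] = {}
    for name, spec in cfg.covariate_marginals.items():
        kind = spec[0]
        if kind == "normal":
            cols[name] = rng.normal(spec[1], spec[2], size=n)
        elif kind == "bernoulli":
            cols[name] = rng.random(n) < spec[1]
        else:
            raise ConfigError(f"unknown marginal kind {kind!r} for {name!r}")
    df = pd.DataFrame(cols)
    # keep physiology plausible without distorting the configured means
    clips = {"age": (18, 100), "bmi": (13, 70), "lvef": (10, 80),
             "potassium": (2.5, 6.5), "magnesium": (1.0, 3.5),
             "creatinine": (0.3, 6.0), "heart_rate": (30, 200),
             "pr_ms": (80, 400), "qrs_ms": (50, 250), "qtc_ms": (300, 650)}
    for name, (lo, hi) in clips.items():
        if name in df:
            df[name] = df[name].clip(lo, hi)
    return df


def _calibrate_success_model(
    X: np.ndarray, target_logors: np.ndarray, target_rate: float
) -> tuple[float, np.ndarray]:
    """Find conditional logistic coefficients whose induced marginal odds
    ratios on the realised design matrix equal the targets.

    The marginal odds ratio of covariate j is computed observationally:
    mean success probability among rows with x_j = 1 vs x_j = 0, on the
    odds scale.  Degenerate (constant) columns keep their target
    coefficient and are dropped from the equation system.
    """
    n, p = X.shape
    active = [j for j in range(p) if 0 < X[:, j].sum() < n]
    Xa = X[:, active]

    def residuals(theta: np.ndarray) -> np.ndarray:
        b0 = theta[0]
        beta = np.array(target_logors, dtype=float)
        beta[active] = theta[1:]
        prob = expit(b0 + X @ beta)
        res = [prob.mean() - target_rate]
        for idx, j in enumerate(active):
            m1 = prob[Xa[:, idx] == 1].mean()
            m0 = prob[Xa[:, idx] == 0].mean()
            res.append((logit(m1) - logit(m0)) - target_logors[j])
        return np.asarray(res)

    x0 = np.concatenate(
        [[logit(target_rate) - X.mean(axis=0) @ target_logors],
         np.asarray(target_logors)[active]]
    )
    sol = root(residuals, x0, method="hybr")
    beta = np.array(target_logors, dtype=float)
    if sol.success:
        beta[active] = sol.x[1:]
        return float(sol.x[0]), beta
    # fall back to target coefficients with a rate-only intercept
    offsets = X @ beta

    def rate_gap(b0: float) -> float:
        return expit(b0 + offsets).mean() - target_rate

    from scipy.optimize import brentq

    b0 = brentq(rate_gap, -30.0, 30.0)
    return float(b0), beta


def generate_cohort(
    config: SynthConfig,
) -> tuple[list[PatientRecord], list[DoseEvent]]:
    """Generate a synthetic cohort of patients and their dose trajectories.

    Deterministic given ``config`` (including its seed).  Dose sequences
    are non-increasing with lengths inside ``n_doses_range``; the
    per-opportunity probability of lowering follows the configured base
    rate plus the QTc excess term; success is drawn from the calibrated
    logistic model and additionally requires at least 5 administrations.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    if n == 0:
        return [], []
    if n < 0:
        raise ConfigError("n_patients must be non-negative")

    cov = _draw_covariates(config, rng)
    cov.insert(0, "patient_id", [f"P{i:05d}" for i in range(n)])

    levels = np.array(DOSE_LEVELS)
    probs = np.array([config.start_dose_probs[d] for d in DOSE_LEVELS])
    start_dose = rng.choice(levels, size=n, p=probs / probs.sum())
    n_doses = rng.integers(config.n_doses_range[0],
                           config.n_doses_range[1] + 1, size=n)

    base_logit = (logit(config.base_adjust_prob)
                  if 0 < config.base_adjust_prob < 1 else None)

    per_patient: list[list[dict]] = []
    any_adjust = np.zeros(n, dtype=bool)
    late_adjust = np.zeros(n, dtype=bool)  # any lowering at position >= 4
    for i in range(n):
        seq = [int(start_dose[i])]
        qtc = [float(cov.at[i, "qtc_ms"])]
        for _ in range(1, int(n_doses[i])):
            drift = config.qtc_drift_per_500 * seq[-1] / 500.0
            qtc.append(qtc[-1] + drift + rng.normal(0.0, config.qtc_noise_sd))
            nxt = seq[-1]
            if seq[-1] > DOSE_LEVELS[-1]:
                if base_logit is None:
                    p_low = config.base_adjust_prob
                else:
                    excess = max(0.0, qtc[-2] - config.adjust_qtc_threshold)
                    p_low = expit(base_logit + config.adjust_qtc_slope * excess)
                if rng.random() < p_low:
                    nxt = int(levels[list(levels).index(seq[-1]) + 1])
                    any_adjust[i] = True
                    if len(seq) + 1 >= 4:
                        late_adjust[i] = True
            seq.append(nxt)
        hr0 = float(cov.at[i, "heart_rate"])
        sinus = bool(cov.at[i, "sinus_rhythm"])
        rows: list[dict] = []
        for t, (dose, q) in enumerate(zip(seq, qtc), start=1):
            hr = float(np.clip(hr0 + rng.normal(0.0, 5.0), 30, 200))
            rr_cbrt = (60.0 / hr) ** (1.0 / 3.0)
            pr = (float(cov.at[i, "pr_ms"]) + rng.normal(0.0, 5.0)
                  if sinus else None)
            rows.append(dict(
                patient_id=cov.at[i, "patient_id"],
                dose_position=t,
                dose_mcg=dose,
                sinus_rhythm=sinus,
                heart_rate=hr,
                pr_ms=pr,
                qrs_ms=float(cov.at[i, "qrs_ms"]) + rng.normal(0.0, 3.0),
                qt_ms=q * rr_cbrt,
                qtc_ms=q,
                creatinine=float(cov.at[i, "creatinine"])
                + rng.normal(0.0, 0.03),
                cardioversions_after=int(rng.poisson(config.cardioversion_rate)),
                action=ACTION_KEEP,
            ))
        per_patient.append(rows)

    # success outcome from the marginally-calibrated logistic model;
    # recognised covariates: start_500, any_adjustment, late_adjustment
    # (lowering at position >= 4) and any boolean patient covariate
    def success_column(name: str) -> np.ndarray:
        if name == "start_500":
            return (start_dose == 500).astype(float)
        if name == "any_adjustment":
            return any_adjust.astype(float)
        if name == "late_adjustment":
            return late_adjust.astype(float)
        spec = config.covariate_marginals.get(name)
        if spec is None or spec[0] != "bernoulli":
            raise ConfigError(
                f"unsupported success-model covariate {name!r}")
        return cov[name].to_numpy(dtype=float)

    order = list(config.success_log_odds)
    design = (np.column_stack([success_column(k) for k in order])
              if order else np.zeros((n, 0)))
    targets = np.array([config.success_log_odds[k] for k in order])
    b0, beta = _calibrate_success_model(design, targets, config.success_rate)
    p_success = expit(b0 + design @ beta)
    success = rng.random(n) < p_success
    success &= n_doses >= 5  # discharge on drug requires >= 5 administrations

    # failed loads may stop at the decisive decrease: the dose produced by
    # the patient's final adjustment is the last one administered
    if config.stop_after_adjustment:
        for i in range(n):
            if success[i] or not any_adjust[i]:
                continue
            rows = per_patient[i]
            last_adj = max(
                (t for t in range(1, len(rows))
                 if rows[t]["dose_mcg"] < rows[t - 1]["dose_mcg"]),
                default=None)
            if last_adj is not None:
                per_patient[i] = rows[: last_adj + 1]

    # realised actions: lower iff the next dose is strictly smaller
    doses_raw: list[dict] = []
    for rows in per_patient:
        for cur, nxt in zip(rows, rows[1:]):
            if nxt["dose_mcg"] < cur["dose_mcg"]:
                cur["action"] = ACTION_LOWER
        doses_raw.extend(rows)

    patients = [
        PatientRecord(
            patient_id=cov.at[i, "patient_id"],
            age=float(cov.at[i, "age"]),
            female=bool(cov.at[i, "female"]),
            bmi=float(cov.at[i, "bmi"]),
            af=bool(cov.at[i, "af"]),
            vt=bool(cov.at[i, "vt"]),
            ppm=bool(cov.at[i, "ppm"]),
            icd=bool(cov.at[i, "icd"]),
            htn=bool(cov.at[i, "htn"]),
            dm=bool(cov.at[i, "dm"]),
            cad=bool(cov.at[i, "cad"]),
            chf=bool(cov.at[i, "chf"]),
            lvef=float(cov.at[i, "lvef"]),
            beta_blocker=bool(cov.at[i, "beta_blocker"]),
            ccb=bool(cov.at[i, "ccb"]),
            potassium=float(cov.at[i, "potassium"]),
            magnesium=float(cov.at[i, "magnesium"]),
            creatinine=float(cov.at[i, "creatinine"]),
            start_dose=int(start_dose[i]),
            success=bool(success[i]),
        )
        for i in range(n)
    ]
    dose_events = [DoseEvent(**d) for d in doses_raw]
    if config.missing_rate > 0:
        dose_events = inject_missingness(
            dose_events, config.missing_rate,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    return patients, dose_events


def inject_missingness(
    doses: list[DoseEvent], rate: float, seed: int
) -> list[DoseEvent]:
    """Blank each maskable numeric field independently with probability
    ``rate``.  Identifiers, dose position/amount and the action are never
    masked; PR intervals already absent (non-sinus rhythm) stay absent.
    """
    if not 0.0 <= rate <= 1.0:
        raise ConfigError(f"missingness rate must lie in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    out = []
    for ev in doses:
        masks = {f: None for f in MASKABLE_FIELDS if rng.random() < rate}
        out.append(replace(ev, **masks) if masks else replace(ev))
    return out


# ---------------------------------------------------------------------------
# table conversion and delimited-text round trip
# ---------------------------------------------------------------------------

def patients_to_frame(patients: list[PatientRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(p) for p in patients], columns=PATIENT_COLUMNS)
    for c in _PATIENT_BOOL:
        df[c] = df[c].astype(int)
    return df


def doses_to_frame(doses: list[DoseEvent]) -> pd.DataFrame:
    df = pd.DataFrame([vars(d) for d in doses], columns=DOSE_COLUMNS)
    df["sinus_rhythm"] = df["sinus_rhythm"].astype(int)
    return df


def frame_to_patients(df: pd.DataFrame) -> list[PatientRecord]:
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        for c in _PATIENT_BOOL:
            d[c] = bool(d[c])
        d["start_dose"] = int(d["start_dose"])
        d["patient_id"] = str(d["patient_id"])
        out.append(PatientRecord(**d))
    return out


def frame_to_doses(df: pd.DataFrame) -> list[DoseEvent]:
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        d["patient_id"] = str(d["patient_id"])
        d["sinus_rhythm"] = bool(d["sinus_rhythm"])
        d["dose_position"] = int(d["dose_position"])
        d["dose_mcg"] = int(d["dose_mcg"])
        d["cardioversions_after"] = int(d["cardioversions_after"])
        for f in MASKABLE_FIELDS:
            v = d[f]
            d[f] = None if pd.isna(v) else float(v)
        out.append(DoseEvent(**d))
    return out


class CohortValidationError(ValueError):
    """Raised when an on-disk cohort violates the schema."""


def validate_cohort(patients: pd.DataFrame, doses: pd.DataFrame) -> None:
    """Schema checks shared by the reader and the generator round trip."""
    bad = set(doses["dose_mcg"].unique()) - set(DOSE_LEVELS)
    if bad:
        raise CohortValidationError(f"dose_mcg outside {DOSE_LEVELS}: {sorted(bad)}")
    bad_action = set(doses["action"].unique()) - {ACTION_KEEP, ACTION_LOWER}
    if bad_action:
        raise CohortValidationError(f"unknown action values: {sorted(bad_action)}")
    for pid, grp in doses.groupby("patient_id", sort=False):
        pos = grp["dose_position"].to_numpy()
        if not np.array_equal(np.sort(pos), np.arange(1, len(pos) + 1)):
            raise CohortValidationError(
                f"patient {pid}: dose positions {sorted(pos)} are not "
                "consecutive from 1"
            )
    pids = set(patients["patient_id"].astype(str))
    orphans = set(doses["patient_id"].astype(str)) - pids
    if orphans:
        raise CohortValidationError(f"doses for unknown patients: {sorted(orphans)[:5]}")


def write_cohort(
    patients: list[PatientRecord], doses: list[DoseEvent], path: str | Path
) -> None:
    """Write ``patients.csv`` and ``doses.csv`` under ``path``.

    Missing values are written as empty fields and booleans as 0/1; the
    float formatting round-trips exactly through :func:`read_cohort`.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    # shortest-repr formatting round-trips float64 exactly
    fmt = lambda v: repr(float(v))  # noqa: E731
    patients_to_frame(patients).to_csv(path / "patients.csv", index=False,
                                       float_format=fmt)
    doses_to_frame(doses).to_csv(path / "doses.csv", index=False,
                                 float_format=fmt)


def read_cohort(path: str | Path) -> tuple[list[PatientRecord], list[DoseEvent]]:
    """Read and validate a cohort written by :func:`write_cohort`."""
    path = Path(path)
    pat_df = _read_table(path / "patients.csv", PATIENT_COLUMNS,
                         numeric=[c for c in PATIENT_COLUMNS if c != "patient_id"])
    dose_df = _read_table(path / "doses.csv", DOSE_COLUMNS,
                          numeric=[c for c in DOSE_COLUMNS
                                   if c not in ("patient_id", "action")])
    validate_cohort(pat_df, dose_df)
    return frame_to_patients(pat_df), frame_to_doses(dose_df)


def _read_table(path: Path, columns: list[str], numeric: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != columns:
        raise CohortValidationError(
            f"{path.name}: header {list(df.columns)} != expected {columns}"
        )
    df = df.replace("", np.nan)
    for col in numeric:
        try:
            # float() parses exactly; pd.to_numeric's fast path is lossy
            df[col] = df[col].map(
                lambda v: np.nan if pd.isna(v) else float(v))
        except (ValueError, TypeError):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()
                     & df[col].notna()].index[0]
            raise CohortValidationError(
                f"{path.name}: non-numeric value in column {col!r}, row {bad}"
            ) from None
    return df
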