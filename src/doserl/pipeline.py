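"""End-to-end orchestration of the analysis stages.

``run_all`` executes simulate -> preprocess -> baselines -> states ->
train-rl -> evaluate, writing every stage's artifacts into one run
directory and aggregating the headline numbers into ``summary.json``.
Reruns with the same configuration produce identical ``summary.json``
bytes; per-stage wall times go to ``run.log`` only.  The base seed fans
out to per-stage derived seeds (seed + stage index) so stages can be rerun
in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from doserl import baselines, preprocess, rl, states, synth

logger = logging.getLogger("doserl")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    split_fraction: float = 0.8
    k_list: tuple[int, ...] = (4, 6, 8)
    primary_k: int = 8
    alpha: float = 0.05
    gamma: float = 0.2
    alphas: tuple[float, ...] = (0.05, 0.1, 0.3)
    gammas: tuple[float, ...] = (0.1, 0.2, 1.0)
    n_epochs: int = 50
    synth: synth.SynthConfig = field(default_factory=synth.SynthConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth_block = raw.pop("synth", {})
        if "start_dose_probs" in synth_block:
            synth_block["start_dose_probs"] = {
                int(k): float(v)
                for k, v in synth_block["start_dose_probs"].items()
            }
        if "n_doses_range" in synth_block:
            synth_block["n_doses_range"] = tuple(synth_block["n_doses_range"])
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        if "seed" not in synth_block:
            synth_block["seed"] = cfg.seed
        cfg.synth = synth.SynthConfig(**synth_block)
        return cfg


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_all(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage into ``out_dir`` and return the summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        summary = _run_stages(config, out)
    except Exception:
        logger.exception("pipeline aborted")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    return summary


def _run_stages(config: RunConfig, out: Path) -> dict:
    t0 = time.perf_counter()
    (out / "config.yaml").write_text(yaml.safe_dump(_config_dict(config)))

    # -- simulate ----------------------------------------------------------
    scfg = dataclasses.replace(config.synth, seed=config.synth.seed)
    patients, doses = synth.generate_cohort(scfg)
    synth.write_cohort(patients, doses, out)
    logger.info("simulate: %d patients, %d doses (%.2fs)",
                len(patients), len(doses), time.perf_counter() - t0)

    # -- preprocess --------------------------------------------------------
    t = time.perf_counter()
    pat_df = synth.patients_to_frame(patients)
    dose_df = synth.doses_to_frame(doses)
    prep = preprocess.preprocess_cohort(
        pat_df, dose_df, fraction=config.split_fraction, seed=config.seed + 1
    )
    feats: preprocess.FeatureMatrix = prep["features"]
    feats.values.to_csv(out / "features.csv", index=False)
    _dump_json({"train_patient_ids": list(prep["split"].train_patient_ids),
                "test_patient_ids": list(prep["split"].test_patient_ids),
                "fraction": config.split_fraction,
                "seed": config.seed + 1}, out / "split.json")
    _dump_json(prep["exclusions"], out / "exclusions.json")
    logger.info("preprocess: %d retained doses, %d excluded patients (%.2fs)",
                len(prep["doses"]), prep["exclusions"]["n_excluded"],
                time.perf_counter() - t)

    # -- baselines ---------------------------------------------------------
    t = time.perf_counter()
    summary = _baseline_stage(config, prep, out)
    logger.info("baselines done (%.2fs)", time.perf_counter() - t)

    # -- states + rl per k -------------------------------------------------
    t = time.perf_counter()
    per_k = {}
    for k in config.k_list:
        per_k[k] = _state_rl_stage(config, prep, k, out,
                                   primary=(k == config.primary_k))
    logger.info("states + rl done (%.2fs)", time.perf_counter() - t)

    summary.update({
        "n_patients": int(len(prep["patients"])),
        "n_doses": int(prep["n_opportunities"]),
        "n_adjustments": int(prep["n_adjust"]),
        "adjustment_rate": prep["n_adjust"] / prep["n_opportunities"],
        "success_rate": float(prep["patients"]["success"].mean()),
        "agreement_by_k": {
            str(k): per_k[k] for k in config.k_list
        },
    })
    _dump_json(summary, out / "summary.json")
    logger.info("pipeline complete (%.2fs total)", time.perf_counter() - t0)
    return summary


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["k_list"] = list(config.k_list)
    d["alphas"] = list(config.alphas)
    d["gammas"] = list(config.gammas)
    d["synth"]["n_doses_range"] = list(config.synth.n_doses_range)
    return d


def _baseline_stage(config: RunConfig, prep: dict, out: Path) -> dict:
    pat = prep["patients"]
    doses = prep["doses"]
    comparisons = baselines.group_comparison_table(pat)
    pd.DataFrame([dataclasses.asdict(c) for c in comparisons]).to_csv(
        out / "table1.csv", index=False)

    per_dose = _per_dose_association_table(pat, doses)
    y = per_dose.pop("success")
    retained, odds = baselines.stepwise_univariate_screen(y, per_dose)
    pd.DataFrame([dataclasses.asdict(o) for o in odds]).assign(
        retained=[o.predictor in retained for o in odds]
    ).to_csv(out / "table2.csv", index=False)

    baselines.regimen_patterns(pat, doses).to_csv(
        out / "fig1_patterns.csv", index=False)

    split = prep["split"]
    feats = prep["features"].values
    is_train = doses["patient_id"].isin(split.train_patient_ids).to_numpy()
    labels = doses["adjustment"].to_numpy()
    metrics = {"naive": dataclasses.asdict(
        baselines.naive_classifier_metrics(labels[~is_train]))}
    if np.unique(labels[is_train]).size == 2:
        models = baselines.fit_classifier_suite(
            feats[is_train], labels[is_train], seed=config.seed + 2)
        reports = baselines.evaluate_suite(models, feats[~is_train],
                                           labels[~is_train])
        metrics.update({k: dataclasses.asdict(v) for k, v in reports.items()})
    _dump_json(metrics, out / "table3.json")
    return {"classifier_metrics": metrics,
            "bonferroni_alpha": baselines.bonferroni_alpha(
                0.05, len(comparisons))}


def _per_dose_association_table(pat: pd.DataFrame,
                                doses: pd.DataFrame) -> pd.DataFrame:
    """Per-dose predictors of loading success (success replicated per dose)."""
    merged = doses.merge(
        pat[["patient_id", "success", "lvef", "chf", "cad", "ppm"]],
        on="patient_id", how="left")
    return pd.DataFrame({
        "success": merged["success"].astype(int),
        "dose_500": (merged["dose_mcg"] == 500).astype(int),
        "dose_250": (merged["dose_mcg"] == 250).astype(int),
        "dose_position": merged["dose_position"],
        "adjustment": merged["adjustment"],
        "sinus_rhythm": merged["sinus_rhythm"].astype(int),
        "ppm": merged["ppm"].astype(int),
        "lvef": merged["lvef"],
        "chf": merged["chf"].astype(int),
        "qrs_ms": merged["qrs_ms"],
        "qtc_ms": merged["qtc_ms"],
        "cad": merged["cad"].astype(int),
    })


def _state_rl_stage(config: RunConfig, prep: dict, k: int, out: Path,
                    primary: bool) -> dict:
    doses = prep["doses"]
    feats = prep["features"].values
    split = prep["split"]
    is_train = doses["patient_id"].isin(split.train_patient_ids).to_numpy()

    model = states.fit_states(feats[is_train], k=k, seed=config.seed + 3)
    assignment = states.assign_states(model, feats)

    train_tr = rl.build_transitions(doses[is_train], assignment[is_train],
                                    prep["patients"])
    test_tr = rl.build_transitions(doses[~is_train], assignment[~is_train],
                                   prep["patients"])
    q = rl.train_tabular(train_tr, n_states=k, alpha=config.alpha,
                         gamma=config.gamma, n_epochs=config.n_epochs)
    agr = rl.evaluate_agreement(q, test_tr)
    result = {"k": k, "n_disagree": agr.n_disagree, "n_total": agr.n_total,
              "disagreement_rate": agr.rate, "agreement_rate": 1 - agr.rate}

    if primary:
        _dump_json({"k": k, "columns": model.columns, "seed": model.seed,
                    "centroids": model.centroids.tolist(),
                    "pca_variances": model.pca_variances.tolist()},
                   out / "state_model.json")
        doses[["patient_id", "dose_position"]].assign(
            state=assignment).to_csv(out / "states.csv", index=False)
        ratios, cumulative = states.pca_profile(feats)
        pd.DataFrame({"component": np.arange(1, len(ratios) + 1),
                      "explained": ratios, "cumulative": cumulative}
                     ).to_csv(out / "fig2_variance.csv", index=False)
        states.profile_states(
            assignment, preprocess.build_feature_table(prep["patients"], doses)
        ).to_csv(out / "table4.csv", index=False)
        q.to_frame().to_csv(out / "q_table.csv", index=False)
        pd.DataFrame([dataclasses.asdict(tr) for tr in train_tr + test_tr]
                     ).to_csv(out / "transitions.csv", index=False)
        _dump_json({"n_disagree": agr.n_disagree, "n_total": agr.n_total,
                    "rate": agr.rate}, out / "agreement.json")
        sweep = rl.hyperparameter_sweep(train_tr, test_tr, n_states=k,
                                        alphas=config.alphas,
                                        gammas=config.gammas,
                                        n_epochs=config.n_epochs)
        pd.DataFrame([{kk: v for kk, v in row.items() if kk != "q_table"}
                      for row in sweep]).assign(
            policy=lambda d: d["policy"].map(lambda p: "-".join(p))
        ).to_csv(out / "sweep.csv", index=False)
    return result


REPORT_FILES = ["table1.csv", "table2.csv", "table3.json", "fig1_patterns.csv",
                "fig2_variance.csv", "table4.csv", "q_table.csv",
                "agreement.json", "summary.json"]


def make_report(run_dir: str | Path) -> str:
    """Render a human-readable markdown report from the stage artifacts.

    Every table is rendered from the files written by :func:`run_all`,
    never recomputed; a missing file raises an error naming it.
    """
    run_dir = Path(run_dir)
    for name in REPORT_FILES:
        if not (run_dir / name).exists():
            raise FileNotFoundError(f"missing stage output: {name}")
    summary = json.loads((run_dir / "summary.json").read_text())
    agreement = json.loads((run_dir / "agreement.json").read_text())
    parts = ["# Dose-loading decision analysis report", ""]
    parts += [
        "## Cohort",
        f"- patients: {summary['n_patients']}",
        f"- doses: {summary['n_doses']}",
        f"- loading success rate: {100 * summary['success_rate']:.1f}%",
        f"- dose-adjustment rate: {100 * summary['adjustment_rate']:.1f}%"
        f" ({summary['n_adjustments']}/{summary['n_doses']})",
        "",
    ]
    for title, name in [("Group comparisons", "table1.csv"),
                        ("Univariate associations with success", "table2.csv"),
                        ("Regimen patterns", "fig1_patterns.csv"),
                        ("PCA variance profile", "fig2_variance.csv"),
                        ("State profiles", "table4.csv"),
                        ("Q table", "q_table.csv")]:
        df = pd.read_csv(run_dir / name)
        parts += [f"## {title}", "", "```", df.to_string(index=False), "```", ""]
    metrics = json.loads((run_dir / "table3.json").read_text())
    parts += ["## Dose-adjustment classifiers", "", "```",
              pd.DataFrame(metrics).T.to_string(), "```", ""]
    parts += [
        "## Greedy-policy agreement (held-out doses)",
        f"- disagreements: {agreement['n_disagree']}/{agreement['n_total']}"
        f" ({100 * agreement['rate']:.1f}%)",
        "- per k: " + ", ".join(
            f"k={k}: {100 * v['agreement_rate']:.1f}%"
            for k, v in summary["agreement_by_k"].items()),
        "",
    ]
    report = "\n".join(parts)
    (run_dir / "report.md").write_text(report)
    return report
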