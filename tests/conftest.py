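"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import math

import pytest

from doserl import preprocess, rl, states, synth


@pytest.fixture(scope="session")
def default_cohort():
    """A cohort at the emulated study scale with default effect sizes."""
    cfg = synth.SynthConfig(n_patients=354, seed=0)
    patients, doses = synth.generate_cohort(cfg)
    return cfg, patients, doses


@pytest.fixture(scope="session")
def late_failure_cohort():
    """Cohort whose loading failures concentrate after dose adjustments,
    worst after late (position >= 4) low-dose ones, with failed loads
    stopping at the decisive decrease -- the regime where the learned
    policy should prefer keeping the dose in late-position states."""
    cfg = synth.SynthConfig(
        n_patients=400,
        seed=11,
        missing_rate=0.0,
        adjust_qtc_slope=0.0,
        base_adjust_prob=0.12,
        success_rate=0.86,
        stop_after_adjustment=True,
        success_log_odds={"any_adjustment": math.log(0.3),
                          "late_adjustment": math.log(0.02)},
    )
    patients, doses = synth.generate_cohort(cfg)
    return cfg, patients, doses


@pytest.fixture(scope="session")
def late_failure_prep(late_failure_cohort):
    _, patients, doses = late_failure_cohort
    return preprocess.preprocess_cohort(
        synth.patients_to_frame(patients), synth.doses_to_frame(doses), seed=12
    )


@pytest.fixture(scope="session")
def late_failure_transitions(late_failure_prep):
    """(train, test) transition logs over k=8 K-means states."""
    prep = late_failure_prep
    feats = prep["features"].values
    doses = prep["doses"]
    is_train = doses["patient_id"].isin(
        prep["split"].train_patient_ids).to_numpy()
    model = states.fit_states(feats[is_train], k=8, seed=13)
    assignment = states.assign_states(model, feats)
    train = rl.build_transitions(doses[is_train], assignment[is_train],
                                 prep["patients"])
    test = rl.build_transitions(doses[~is_train], assignment[~is_train],
                                prep["patients"])
    return train, test
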