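"""Transition building, SARSA updates, training, greedy evaluation."""

from __future__ import annotations

import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from doserl.rl import (
    ACTION_KEEP,
    ACTION_LOWER,
    QTable,
    Transition,
    build_transitions,
    evaluate_agreement,
    greedy_action,
    hyperparameter_sweep,
    sarsa_update,
    train_linear,
    train_tabular,
)


def _cohort(sequences, successes):
    """Tiny dose log: {pid: [dose amounts]} plus success flags."""
    pats = pd.DataFrame({"patient_id": list(sequences),
                         "success": successes})
    rows = []
    for pid, seq in sequences.items():
        for t, d in enumerate(seq, start=1):
            rows.append({"patient_id": pid, "dose_position": t, "dose_mcg": d})
    return pats, pd.DataFrame(rows)


def oracle_train(transitions, n_states, alpha, gamma, n_epochs):
    """Independent step-by-step reference: plain dict of Q values updated
    one transition at a time with the printed update rule."""
    Q = {(s, a): 0.0 for s in range(n_states)
         for a in (ACTION_KEEP, ACTION_LOWER)}
    for _ in range(n_epochs):
        for tr in transitions:
            nxt = 0.0 if tr.terminal else Q[(tr.next_state, tr.next_action)]
            key = (tr.state, tr.action)
            Q[key] = Q[key] + alpha * ((tr.reward + gamma * nxt) - Q[key])
    return Q


def _random_log(rng, n_states=3, max_len=10):
    """Random structurally-valid episode log of at most max_len transitions."""
    out = []
    remaining = rng.randint(1, max_len)
    while remaining > 0:
        ep_len = rng.randint(1, remaining)
        states = [rng.randrange(n_states) for _ in range(ep_len)]
        actions = [rng.choice((ACTION_KEEP, ACTION_LOWER))
                   for _ in range(ep_len)]
        failed = rng.random() < 0.5
        for t in range(ep_len):
            last = t == ep_len - 1
            out.append(Transition(
                state=states[t], action=actions[t],
                reward=-10.0 if (last and failed) else 0.0,
                next_state=None if last else states[t + 1],
                next_action=None if last else actions[t + 1],
                terminal=last))
        remaining -= ep_len
    return out


class TestBuildTransitions:
    def test_successful_patient_all_zero_rewards(self):
        pats, doses = _cohort({"a": [500] * 5}, [1])
        trs = build_transitions(doses, np.arange(5), pats)
        assert len(trs) == 5
        assert all(tr.reward == 0.0 for tr in trs)
        assert [tr.terminal for tr in trs] == [False] * 4 + [True]
        assert trs[-1].next_state is None and trs[-1].next_action is None

    def test_failed_patient_penalized_on_last_dose(self):
        pats, doses = _cohort({"a": [500, 500, 500]}, [0])
        trs = build_transitions(doses, np.zeros(3, dtype=int), pats)
        assert [tr.reward for tr in trs] == [0.0, 0.0, -10.0]
        assert trs[-1].action == ACTION_KEEP

    def test_failed_patient_stopping_after_decrease_logs_lower(self):
        # the stop culminates the lowering decision
        pats, doses = _cohort({"a": [500, 500, 250]}, [0])
        trs = build_transitions(doses, np.zeros(3, dtype=int), pats)
        assert trs[1].action == ACTION_LOWER  # 500 -> 250
        assert trs[2].action == ACTION_LOWER  # terminal after the decrease
        assert trs[2].reward == -10.0

    def test_successful_patient_final_action_keeps_by_convention(self):
        pats, doses = _cohort({"a": [500, 500, 250, 250, 250]}, [1])
        trs = build_transitions(doses, np.zeros(5, dtype=int), pats)
        assert [tr.action for tr in trs] == [
            ACTION_KEEP, ACTION_LOWER, ACTION_KEEP, ACTION_KEEP, ACTION_KEEP]

    def test_empty_log(self):
        pats, doses = _cohort({}, [])
        doses = pd.DataFrame(columns=["patient_id", "dose_position",
                                      "dose_mcg"])
        assert build_transitions(doses, np.array([]), pats) == []

    def test_unassigned_state_raises(self):
        pats, doses = _cohort({"a": [500, 500]}, [1])
        with pytest.raises(ValueError):
            build_transitions(doses, np.array([0.0, np.nan]), pats)

    def test_terminal_flag_must_match_next_state(self):
        with pytest.raises(ValueError):
            Transition(state=0, action=ACTION_KEEP, reward=0.0,
                       next_state=1, next_action=ACTION_KEEP, terminal=True)


class TestSarsaUpdate:
    @pytest.mark.parametrize("q_old,r,q_next,alpha,gamma,expected", [
        (0.0, -10.0, 0.0, 0.05, 0.2, -0.5),
        (0.0, 0.0, 0.0, 0.1, 0.5, 0.0),
        (-1.0, 0.0, -2.0, 0.1, 0.5, -1.0),
    ])
    def test_hand_computed_values(self, q_old, r, q_next, alpha, gamma,
                                  expected):
        assert sarsa_update(q_old, r, q_next, alpha, gamma) == pytest.approx(
            expected, abs=1e-12)

    @settings(derandomize=True, max_examples=80)
    @given(
        q_old=st.floats(-20, 0), q_next=st.floats(-20, 0),
        r=st.sampled_from([0.0, -10.0]),
        alpha=st.floats(0.01, 1.0), gamma=st.floats(0.0, 1.0),
    )
    def test_update_interpolates_toward_the_target(self, q_old, q_next, r,
                                                   alpha, gamma):
        target = r + gamma * q_next
        new = sarsa_update(q_old, r, q_next, alpha, gamma)
        assert new == pytest.approx(q_old + alpha * (target - q_old),
                                    rel=1e-12, abs=1e-12)
        lo, hi = min(q_old, target), max(q_old, target)
        assert lo - 1e-9 <= new <= hi + 1e-9


class TestTrainTabular:
    def test_single_failed_transition_one_epoch(self):
        trs = [Transition(state=0, action=ACTION_KEEP, reward=-10.0,
                          next_state=None, next_action=None, terminal=True)]
        q = train_tabular(trs, n_states=2, alpha=0.05, gamma=0.2, n_epochs=1)
        assert q.values[0, 0] == pytest.approx(-0.5, abs=1e-12)
        assert np.all(q.values.ravel()[1:] == 0.0)

    def test_zero_rewards_leave_q_at_zero(self):
        rng = random.Random(0)
        trs = [tr for tr in _random_log(rng, max_len=10)]
        trs = [Transition(**{**vars(tr), "reward": 0.0}) for tr in trs]
        q = train_tabular(trs, n_states=3, alpha=0.3, gamma=0.9, n_epochs=20)
        assert np.all(q.values == 0.0)

    def test_matches_step_by_step_oracle_on_random_small_logs(self):
        for trial in range(60):
            rng = random.Random(trial)
            trs = _random_log(rng)
            alpha = rng.choice((0.05, 0.1, 0.3))
            gamma = rng.choice((0.1, 0.5, 1.0))
            epochs = rng.randint(1, 4)
            q = train_tabular(trs, n_states=3, alpha=alpha, gamma=gamma,
                              n_epochs=epochs, tolerance=0.0)
            ref = oracle_train(trs, 3, alpha, gamma, epochs)
            for (s, a), v in ref.items():
                assert q.q(s, a) == pytest.approx(v, abs=1e-12)

    def test_values_never_positive(self):
        for epochs in (1, 3, 10):
            rng = random.Random(99)
            trs = _random_log(rng, max_len=10)
            q = train_tabular(trs, n_states=3, alpha=0.3, gamma=1.0,
                              n_epochs=epochs)
            assert np.all(q.values <= 1e-12)

    def test_two_state_toy_log_hand_oracle(self):
        # 3 transitions x 2 epochs = 6 updates, checked against the
        # independently coded sequential reference
        trs = [
            Transition(0, ACTION_KEEP, 0.0, 1, ACTION_LOWER, False),
            Transition(1, ACTION_LOWER, 0.0, 1, ACTION_KEEP, False),
            Transition(1, ACTION_KEEP, -10.0, None, None, True),
        ]
        q = train_tabular(trs, n_states=2, alpha=0.1, gamma=0.5, n_epochs=2,
                          tolerance=0.0)
        ref = oracle_train(trs, 2, 0.1, 0.5, 2)
        for (s, a), v in ref.items():
            assert q.q(s, a) == pytest.approx(v, abs=1e-12)

    def test_invalid_hyperparameters_raise(self):
        trs = [Transition(0, ACTION_KEEP, 0.0, None, None, True)]
        with pytest.raises(ValueError):
            train_tabular(trs, 1, alpha=0.0)
        with pytest.raises(ValueError):
            train_tabular(trs, 1, gamma=1.5)
        with pytest.raises(ValueError):
            train_tabular([], 1)


class TestTrainLinear:
    def test_one_hot_features_reduce_to_tabular(self):
        rng = random.Random(17)
        trs = _random_log(rng, n_states=4, max_len=10)
        q = train_tabular(trs, 4, alpha=0.1, gamma=0.5, n_epochs=3,
                          tolerance=0.0)
        lin = train_linear(trs, np.eye(4), alpha=0.1, gamma=0.5, n_epochs=3)
        assert not lin.diverged
        for s in range(4):
            for a in (ACTION_KEEP, ACTION_LOWER):
                assert lin.q(np.eye(4)[s], a) == pytest.approx(
                    q.q(s, a), abs=1e-9)

    def test_zero_rewards_leave_weights_zero(self):
        trs = [Transition(0, ACTION_KEEP, 0.0, 0, ACTION_KEEP, False),
               Transition(0, ACTION_KEEP, 0.0, None, None, True)]
        lin = train_linear(trs, np.eye(1), alpha=0.3, gamma=1.0, n_epochs=10)
        assert np.all(lin.weights == 0.0)

    def test_large_feature_norm_sets_divergence_flag(self):
        # |x|^2 = 100 with alpha = 0.3 makes each terminal update overshoot
        # by a factor of -29: oscillating blow-up, flagged not raised
        trs = [Transition(0, ACTION_KEEP, -10.0, None, None, True)]
        lin = train_linear(trs, np.array([[10.0]]), alpha=0.3, gamma=0.2,
                           n_epochs=50)
        assert lin.diverged
        assert np.all(np.isfinite(lin.weights) | True)  # no crash

    def test_dimension_mismatch_raises(self):
        trs = [Transition(5, ACTION_KEEP, 0.0, None, None, True)]
        with pytest.raises(ValueError):
            train_linear(trs, np.eye(2))


class TestGreedyAndAgreement:
    def _qtable(self, rows):
        return QTable(values=np.array(rows, dtype=float), alpha=0.05,
                      gamma=0.2)

    @pytest.mark.parametrize("keep,lower,expected", [
        (-0.227, -2.26, ACTION_KEEP),
        (0.0, 0.0, ACTION_KEEP),      # exact tie breaks to keep
        (-0.021, 0.0, ACTION_LOWER),
    ])
    def test_greedy_action(self, keep, lower, expected):
        q = self._qtable([[keep, lower]])
        assert greedy_action(q, 0) == expected

    def test_zero_table_disagreement_equals_adjustment_rate(
            self, late_failure_transitions):
        _, test = late_failure_transitions
        q = self._qtable(np.zeros((8, 2)))
        agr = evaluate_agreement(q, test)
        observed = np.mean([tr.action == ACTION_LOWER for tr in test])
        assert agr.rate == pytest.approx(observed, abs=1e-12)

    def test_perfect_and_inverted_policies(self):
        trs = [Transition(s, ACTION_KEEP, 0.0, None, None, True)
               for s in range(5)]
        match = self._qtable([[0.0, -1.0]] * 5)
        agr = evaluate_agreement(match, trs)
        assert (agr.n_disagree, agr.n_total, agr.rate) == (0, 5, 0.0)
        invert = self._qtable([[-1.0, 0.0]] * 5)
        agr = evaluate_agreement(invert, trs)
        assert (agr.n_disagree, agr.n_total, agr.rate) == (5, 5, 1.0)

    def test_empty_test_set_raises(self):
        with pytest.raises(ValueError):
            evaluate_agreement(self._qtable([[0.0, 0.0]]), [])


class TestSweep:
    def test_single_cell_grid(self, late_failure_transitions):
        train, test = late_failure_transitions
        rows = hyperparameter_sweep(train, test, n_states=8,
                                    alphas=[0.05], gammas=[0.2])
        assert len(rows) == 1
        assert rows[0]["alpha"] == 0.05 and rows[0]["gamma"] == 0.2

    def test_absolute_values_differ_but_signs_agree_across_alphas(
            self, late_failure_transitions):
        train, _ = late_failure_transitions
        tables = {a: train_tabular(train, 8, alpha=a, gamma=0.2, n_epochs=50)
                  for a in (0.05, 0.3)}
        assert not np.allclose(tables[0.05].values, tables[0.3].values)
        assert np.array_equal(np.sign(np.round(tables[0.05].values, 10)),
                              np.sign(np.round(tables[0.3].values, 10)))
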