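"""Offline SARSA on logged dosing decisions.

Each administered dose becomes one transition of an episodic Markov
decision process: the state is the K-means cluster of the dose's feature
vector, the action is what the clinician did afterwards (``keep`` the dose
or ``lower`` it), and the reward is 0 everywhere except the final dose of
a patient whose loading failed, which receives -10.  Because the data are
a fixed log, learning is a batch of repeated on-policy temporal-difference
sweeps:

    Q(S_t, A_t) <- Q(S_t, A_t)
                   + alpha * [R_t + gamma * Q(S_{t+1}, A_{t+1}) - Q(S_t, A_t)]

with Q identically 0 at initialisation and Q(terminal, .) = 0.  With
rewards in {0, -10} and zero initialisation every tabular value stays
<= 0.  A linear action-value variant (semi-gradient updates on state
features; with one-hot state features it reduces exactly to the tabular
sweep) is provided for comparison, with a divergence flag instead of a
crash when weights blow up.

The learned policy is evaluated by greedy-action agreement with the logged
clinician decisions on held-out patients; exact ties break to ``keep``,
the overwhelmingly more common action.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from doserl.synth import ACTION_KEEP, ACTION_LOWER

ACTIONS = (ACTION_KEEP, ACTION_LOWER)
_A_INDEX = {ACTION_KEEP: 0, ACTION_LOWER: 1}
FAILURE_REWARD = -10.0


@dataclass(frozen=True)
class Transition:
    """One dosing decision as a SARSA quintuple."""

    state: int
    action: str
    reward: float
    next_state: Optional[int]  # None at episode end
    next_action: Optional[str]
    terminal: bool
    patient_id: str = ""
    dose_position: int = 0

    def __post_init__(self) -> None:
        if self.terminal != (self.next_state is None):
            raise ValueError("terminal flag must match a missing next state")
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")


def build_transitions(
    doses: pd.DataFrame, assignment: np.ndarray, patients: pd.DataFrame
) -> list[Transition]:
    """Turn the per-dose log into SARSA transitions, one per dose.

    ``assignment`` is row-aligned with ``doses``.  The action at each
    position is ``lower`` iff the next dose amount is strictly smaller.
    The final transition of each patient is terminal and carries reward
    -10 iff that patient's loading failed.  The final position has no
    subsequent dose, so its logged action is ``keep`` by convention --
    except for a failed patient whose last recorded dose was itself a
    decrease from the previous one: there the stop is the culmination of
    the lowering decision, and the terminal action is ``lower``.
    """
    assignment = np.asarray(assignment)
    if len(assignment) != len(doses):
        raise ValueError("state assignment must align with the dose rows")
    if np.any(pd.isna(assignment)):
        raise ValueError("every dose needs an assigned state")
    success = dict(zip(patients["patient_id"].astype(str),
                       patients["success"].astype(bool)))
    df = doses.copy()
    df["_state"] = assignment.astype(int)
    df = df.sort_values(["patient_id", "dose_position"])
    out: list[Transition] = []
    for pid, grp in df.groupby("patient_id", sort=True):
        states = grp["_state"].to_list()
        amounts = grp["dose_mcg"].to_list()
        positions = grp["dose_position"].to_list()
        n = len(grp)
        actions = [
            ACTION_LOWER if t + 1 < n and amounts[t + 1] < amounts[t]
            else ACTION_KEEP
            for t in range(n)
        ]
        failed = not success[str(pid)]
        if failed and n >= 2 and amounts[-1] < amounts[-2]:
            actions[-1] = ACTION_LOWER
        for t in range(n):
            last = t == n - 1
            out.append(Transition(
                state=int(states[t]),
                action=actions[t],
                reward=FAILURE_REWARD if (last and failed) else 0.0,
                next_state=None if last else int(states[t + 1]),
                next_action=None if last else actions[t + 1],
                terminal=last,
                patient_id=str(pid),
                dose_position=int(positions[t]),
            ))
    return out


def sarsa_update(
    q_old: float, reward: float, q_next: float, alpha: float, gamma: float
) -> float:
    """One temporal-difference update toward reward + gamma * q_next."""
    return q_old + alpha * ((reward + gamma * q_next) - q_old)


@dataclass
class QTable:
    """Tabular action values: one row per state, columns (keep, lower)."""

    values: np.ndarray
    alpha: float
    gamma: float
    epochs_run: int = 0

    def q(self, state: int, action: str) -> float:
        return float(self.values[state, _A_INDEX[action]])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"state": s, "action": a, "value": float(self.values[s, i]),
             "alpha": self.alpha, "gamma": self.gamma}
            for s in range(self.values.shape[0])
            for a, i in _A_INDEX.items()
        ]
        return pd.DataFrame(rows)


def _check_hyperparams(alpha: float, gamma: float) -> None:
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must lie in [0, 1], got {gamma}")


def train_tabular(
    transitions: Sequence[Transition],
    n_states: int,
    alpha: float = 0.05,
    gamma: float = 0.2,
    n_epochs: int = 50,
    tolerance: float = 1e-8,
) -> QTable:
    """Batch tabular SARSA: repeated in-order sweeps over the logged
    transitions until the largest per-sweep change drops below the
    tolerance or the epoch budget runs out.

    The sweep visits patients in id order and doses in position order
    (the order in which :func:`build_transitions` emits them).
    """
    _check_hyperparams(alpha, gamma)
    if not transitions:
        raise ValueError("cannot train on an empty transition log")
    Q = np.zeros((n_states, 2))
    epochs = 0
    for _ in range(n_epochs):
        max_delta = 0.0
        for tr in transitions:
            q_next = 0.0 if tr.terminal else Q[tr.next_state,
                                               _A_INDEX[tr.next_action]]
            i, j = tr.state, _A_INDEX[tr.action]
            new = sarsa_update(Q[i, j], tr.reward, q_next, alpha, gamma)
            max_delta = max(max_delta, abs(new - Q[i, j]))
            Q[i, j] = new
        epochs += 1
        if max_delta < tolerance:
            break
    return QTable(values=Q, alpha=alpha, gamma=gamma, epochs_run=epochs)


@dataclass
class LinearQ:
    """Linear action values: one weight vector per action over state
    features; ``diverged`` flags a blow-up instead of raising."""

    weights: np.ndarray  # (2, n_features)
    alpha: float
    gamma: float
    diverged: bool = False

    def q(self, features: np.ndarray, action: str) -> float:
        return float(self.weights[_A_INDEX[action]] @ np.asarray(features))


def train_linear(
    transitions: Sequence[Transition],
    state_features: np.ndarray,
    alpha: float = 0.05,
    gamma: float = 0.2,
    n_epochs: int = 50,
    off_policy: bool = False,
    divergence_bound: float = 1e6,
) -> LinearQ:
    """Semi-gradient SARSA with a linear action-value function.

    ``state_features`` maps state id -> feature vector (rows of the
    matrix); the default pipeline passes an identity matrix, for which the
    update sequence coincides exactly with the tabular sweep.  The target
    uses the logged next action (on-policy); ``off_policy=True`` bootstraps
    from the max over actions instead (Q-learning).  Weights beyond the
    divergence bound stop the training and set ``diverged``.
    """
    _check_hyperparams(alpha, gamma)
    F = np.asarray(state_features, dtype=float)
    if not transitions:
        raise ValueError("cannot train on an empty transition log")
    if F.ndim != 2:
        raise ValueError("state_features must be a 2-D matrix")
    if F.shape[0] <= max(tr.state for tr in transitions):
        raise ValueError("state_features has fewer rows than state ids")
    W = np.zeros((2, F.shape[1]))
    diverged = False
    for _ in range(n_epochs):
        for tr in transitions:
            x = F[tr.state]
            if tr.terminal:
                q_next = 0.0
            elif off_policy:
                q_next = max(W[0] @ F[tr.next_state], W[1] @ F[tr.next_state])
            else:
                q_next = W[_A_INDEX[tr.next_action]] @ F[tr.next_state]
            j = _A_INDEX[tr.action]
            td_error = (tr.reward + gamma * q_next) - W[j] @ x
            W[j] = W[j] + alpha * td_error * x
            if not np.all(np.isfinite(W)) or np.abs(W).max() > divergence_bound:
                diverged = True
                break
        if diverged:
            break
    return LinearQ(weights=W, alpha=alpha, gamma=gamma, diverged=diverged)


def greedy_action(q: QTable, state: int) -> str:
    """Argmax action; an exact tie breaks to ``keep`` (the majority
    clinician decision)."""
    keep, lower = q.values[state, 0], q.values[state, 1]
    return ACTION_KEEP if keep >= lower else ACTION_LOWER


@dataclass
class AgreementResult:
    n_disagree: int
    n_total: int
    rate: float  # disagreement fraction


def evaluate_agreement(
    q: QTable, test_transitions: Sequence[Transition]
) -> AgreementResult:
    """Fraction of held-out dosing decisions where the greedy policy
    disagrees with the clinician's logged action."""
    if not test_transitions:
        raise ValueError("empty test transition set")
    n_disagree = sum(1 for tr in test_transitions
                     if greedy_action(q, tr.state) != tr.action)
    n = len(test_transitions)
    return AgreementResult(n_disagree, n, n_disagree / n)


def hyperparameter_sweep(
    train_transitions: Sequence[Transition],
    test_transitions: Sequence[Transition],
    n_states: int,
    alphas: Sequence[float] = (0.05, 0.1, 0.3),
    gammas: Sequence[float] = (0.1, 0.2, 1.0),
    n_epochs: int = 50,
) -> list[dict]:
    """Train and evaluate one tabular model per (alpha, gamma) cell.

    The absolute Q values change across cells but, on well-behaved logs,
    the greedy policy (and hence the agreement rate) does not.
    """
    rows = []
    for alpha in alphas:
        for gamma in gammas:
            q = train_tabular(train_transitions, n_states,
                              alpha=alpha, gamma=gamma, n_epochs=n_epochs)
            agr = evaluate_agreement(q, test_transitions)
            rows.append({
                "alpha": alpha,
                "gamma": gamma,
                "n_disagree": agr.n_disagree,
                "n_total": agr.n_total,
                "disagreement_rate": agr.rate,
                "q_table": q,
                "policy": tuple(greedy_action(q, s) for s in range(n_states)),
            })
    return rows
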