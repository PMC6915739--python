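"""Model-based (FORWARD) and model-free (SARSA) learners.

The FORWARD learner estimates the state-transition matrix with a delta rule
driven by state-prediction errors (SPE = 1 - estimated probability of the
observed transition) and plans action values by backward induction through
the two-stage tree every trial, since token values change trial to trial.

The SARSA learner caches action values updated by reward-prediction errors.
Three goal-driven variants exist: a single shared table (``1MF``), a
state x action x goal table with one learning rate (``3Q``), and three fully
independent tables with separate learning rates (``3MF``); the goal context
of a trial is the token currently carrying the maximum value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ACTION_INDEX, COMPLEXITY_LEVELS, TOKENS
from .task_env import (
    NONE_TOKEN_IDX,
    N_STATES,
    STAGE2_STATES,
    START_STATE,
    StateSpaceModel,
)

MF_TYPES = ("1MF", "3Q", "3MF")


def goal_context(token_values: np.ndarray) -> int:
    """Index of the goal token (argmax value); ties broken by the fixed
    token order red < blue < silver (first maximum wins)."""
    return int(np.argmax(token_values))


def goal_change(token_values_t: np.ndarray, token_values_prev: np.ndarray | None) -> int:
    """1 iff the argmax token kind differs from the previous trial
    (0 on the first trial of a session by convention)."""
    if token_values_prev is None:
        return 0
    return int(goal_context(token_values_t) != goal_context(token_values_prev))


@dataclass
class ForwardLearner:
    """FORWARD model-based learner: transition estimation + planning."""

    model: StateSpaceModel
    eta_mb: float
    T_hat: np.ndarray = field(init=False)  # (N_STATES, 4) prob of first-listed successor

    def __post_init__(self) -> None:
        if not 0.0 <= self.eta_mb <= 1.0:
            raise ValueError("eta_mb must lie in [0, 1]")
        self.reset()

    def reset(self) -> None:
        # uniform prior over the two successors of every valid (s, a)
        self.T_hat = np.where(self.model.succ[:, :, 0] >= 0, 0.5, np.nan)

    def prob_of(self, s: int, a_idx: int, s_next: int) -> float:
        pair = self.model.succ[s, a_idx]
        if s_next == pair[0]:
            return float(self.T_hat[s, a_idx])
        if s_next == pair[1]:
            return float(1.0 - self.T_hat[s, a_idx])
        raise ValueError(f"state {s_next} is not a successor of ({s}, {a_idx})")

    def observe(self, s: int, a_idx: int, s_next: int) -> float:
        """Delta-rule update toward the observed successor; returns the SPE.

        The observed entry moves up by ``eta_mb * spe`` and the sibling entry
        down by the same amount, so the row stays on the simplex.
        """
        p_obs = self.prob_of(s, a_idx, s_next)
        spe = 1.0 - p_obs
        pair = self.model.succ[s, a_idx]
        if s_next == pair[0]:
            self.T_hat[s, a_idx] += self.eta_mb * spe
        else:
            self.T_hat[s, a_idx] -= self.eta_mb * spe
        return spe

    def plan(self, token_values: np.ndarray, complexity: str) -> np.ndarray:
        """Backward induction over the two-stage tree under ``T_hat``.

        Outcome value = token value x reward_prob ("none" outcomes are 0);
        stage-2 Q = expected outcome value; stage-1 Q = expected maximum over
        the stage-2 actions available under the block's complexity.
        Returns a (N_STATES, 4) array (NaN where undefined).
        """
        return plan_q(
            self.model, self.T_hat, token_values, complexity, self.model.reward_prob
        )


def plan_q(
    model: StateSpaceModel,
    T_first: np.ndarray,
    token_values: np.ndarray,
    complexity: str,
    reward_prob: float,
) -> np.ndarray:
    """Two-stage backward induction given P(first-listed successor) rows."""
    c = COMPLEXITY_LEVELS.index(complexity)
    token_vals4 = np.append(np.asarray(token_values, float), 0.0)  # none -> 0
    v_out = np.zeros(N_STATES)
    outcome_mask = model.token_idx >= 0
    v_out[outcome_mask] = token_vals4[model.token_idx[outcome_mask]] * reward_prob

    Q = np.full((N_STATES, 4), np.nan)
    for s in STAGE2_STATES:
        for a in range(4):
            if model.succ[s, a, 0] < 0:
                continue
            p = T_first[s, a]
            Q[s, a] = p * v_out[model.succ[s, a, 0]] + (1 - p) * v_out[model.succ[s, a, 1]]
    best2 = np.zeros(N_STATES)
    for s in STAGE2_STATES:
        avail = model.avail[c, s]
        best2[s] = np.nanmax(np.where(avail, Q[s], np.nan))
    for a in range(4):
        if model.succ[START_STATE, a, 0] < 0:
            continue
        p = T_first[START_STATE, a]
        s_a, s_b = model.succ[START_STATE, a]
        Q[START_STATE, a] = p * best2[s_a] + (1 - p) * best2[s_b]
    return Q


@dataclass
class SarsaLearner:
    """Model-free SARSA learner with optional goal-context value tables.

    ``etas`` holds one learning rate for ``1MF``/``3Q`` and three (red, blue,
    silver) for ``3MF``.  Q tables initialize at zero.
    """

    mf_type: str
    etas: tuple[float, ...]
    Q: np.ndarray = field(init=False)  # (n_tables, N_STATES, 4)

    def __post_init__(self) -> None:
        if self.mf_type not in MF_TYPES:
            raise ValueError(f"mf_type must be one of {MF_TYPES}")
        n_eta = 3 if self.mf_type == "3MF" else 1
        if len(self.etas) != n_eta:
            raise ValueError(f"{self.mf_type} requires exactly {n_eta} learning rate(s)")
        if any(not 0.0 <= e <= 1.0 for e in self.etas):
            raise ValueError("learning rates must lie in [0, 1]")
        self.reset()

    def reset(self) -> None:
        n_tables = 1 if self.mf_type == "1MF" else 3
        self.Q = np.zeros((n_tables, N_STATES, 4))

    def _table(self, goal: int) -> int:
        if self.mf_type == "1MF":
            return 0
        if not 0 <= goal <= 2:
            raise ValueError(f"unknown goal context {goal}")
        return goal

    def _eta(self, goal: int) -> float:
        return self.etas[goal] if self.mf_type == "3MF" else self.etas[0]

    def values(self, goal: int, s: int) -> np.ndarray:
        return self.Q[self._table(goal), s]

    def update(
        self,
        goal: int,
        s: int,
        a_idx: int,
        r: float,
        s_next: int | None = None,
        a_next_idx: int | None = None,
    ) -> float:
        """One SARSA update; terminal when ``s_next`` is None.  Returns the RPE
        ``r + Q(s', a') - Q(s, a)`` (bootstrap term 0 at terminal states)."""
        t = self._table(goal)
        bootstrap = 0.0
        if s_next is not None:
            if a_next_idx is None:
                raise ValueError("a_next_idx required for non-terminal updates")
            bootstrap = self.Q[t, s_next, a_next_idx]
        rpe = r + bootstrap - self.Q[t, s, a_idx]
        self.Q[t, s, a_idx] += self._eta(goal) * rpe
        return float(rpe)
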