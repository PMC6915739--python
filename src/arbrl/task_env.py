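"""Two-stage MDP environment: state space, block schedule, token draws, steps.

State ids: 1 (start), 2-3 (second stage), 4-11 (outcome).  Every (state,
action) pair maps to an ordered pair of successor states; the block's
uncertainty condition sets the probability of the first-listed successor
(0.9 low uncertainty, 0.5 high).  Outcome states pay their token's current
value with probability ``reward_prob``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import (
    ACTIONS,
    ACTION_INDEX,
    COMPLEXITY_LEVELS,
    ConfigError,
    NO_TOKEN,
    N_STATES,
    OUTCOME_STATES,
    STAGE2_STATES,
    START_STATE,
    TOKEN_INDEX,
    TOKENS,
    TaskConfig,
    UNCERTAINTY_LEVELS,
)

#: token index used for unlabelled ("none") outcomes in array form
NONE_TOKEN_IDX = 3


@dataclass(frozen=True)
class StateSpaceModel:
    """The true generative state space in array form.

    ``succ[s, a]`` is the ordered successor pair for state ``s`` and action
    index ``a`` (-1 where invalid); ``token_idx[s]`` maps outcome states to
    token indices (0 red, 1 blue, 2 silver, 3 none; -1 for non-outcome
    states); ``avail[c]`` is the (state, action) availability mask for
    complexity condition ``c`` (0 low, 1 high).
    """

    succ: np.ndarray          # (N_STATES, 4, 2) int
    token_idx: np.ndarray     # (N_STATES,) int
    avail: np.ndarray         # (2, N_STATES, 4) bool
    reward_prob: float
    config: TaskConfig = field(repr=False)

    def available_actions(self, state: int, complexity: str) -> tuple[str, ...]:
        c = COMPLEXITY_LEVELS.index(complexity)
        return tuple(a for i, a in enumerate(ACTIONS) if self.avail[c, state, i])

    def successors(self, state: int, action: str) -> tuple[int, int]:
        pair = self.succ[state, ACTION_INDEX[action]]
        if pair[0] < 0:
            raise ValueError(f"no transition defined for state {state}, action {action}")
        return int(pair[0]), int(pair[1])


@dataclass(frozen=True)
class BlockCondition:
    """One block of the schedule: an (uncertainty, complexity) cell."""

    uncertainty: str   # "low" -> p=(0.9,0.1), "high" -> (0.5,0.5)
    complexity: str    # "low" -> 2 stage-2 options, "high" -> 4
    transition_prob: tuple[float, float]
    n_trials: int

    def __post_init__(self) -> None:
        if abs(sum(self.transition_prob) - 1.0) > 1e-12:
            raise ConfigError("transition probability pair must sum to 1")


def build_state_space(config: TaskConfig | None = None) -> StateSpaceModel:
    """Construct and validate the generative state space from a config.

    Deterministic for a given config; raises :class:`ConfigError` if the
    token map leaves an outcome state unlabelled, a token kind unused, or the
    wiring leaves an outcome state unreachable.
    """
    config = config or TaskConfig()

    succ = np.full((N_STATES, 4, 2), -1, dtype=np.int64)
    for state, acts in config.wiring.items():
        for action, pair in acts.items():
            if len(pair) != 2:
                raise ConfigError(f"({state},{action}) must map to exactly 2 successors")
            succ[state, ACTION_INDEX[action]] = pair

    token_idx = np.full(N_STATES, -1, dtype=np.int64)
    for s in OUTCOME_STATES:
        label = config.token_map.get(s)
        if label is None:
            raise ConfigError(f"outcome state {s} has no token label")
        if label == NO_TOKEN:
            token_idx[s] = NONE_TOKEN_IDX
        elif label in TOKEN_INDEX:
            token_idx[s] = TOKEN_INDEX[label]
        else:
            raise ConfigError(f"unknown token label {label!r} for state {s}")
    used = set(config.token_map.values())
    for kind in (*TOKENS, NO_TOKEN):
        if kind not in used:
            raise ConfigError(f"token kind {kind!r} labels no outcome state")

    low_set = set(config.low_complexity_actions)
    if not low_set <= set(ACTIONS):
        raise ConfigError("low-complexity action set must be a subset of the four actions")
    avail = np.zeros((2, N_STATES, 4), dtype=bool)
    for i, a in enumerate(ACTIONS):
        defined1 = succ[START_STATE, i, 0] >= 0
        # start state: always exactly the two low-complexity actions
        avail[:, START_STATE, i] = defined1 and a in low_set
        for s in STAGE2_STATES:
            defined = succ[s, i, 0] >= 0
            avail[1, s, i] = defined
            avail[0, s, i] = defined and a in low_set

    if avail[0, START_STATE].sum() != 2:
        raise ConfigError("start state must offer exactly 2 actions")
    for s in STAGE2_STATES:
        if avail[0, s].sum() != 2 or avail[1, s].sum() != 4:
            raise ConfigError(
                f"stage-2 state {s} must offer 2 (low) / 4 (high complexity) actions"
            )
    reachable = {
        int(x)
        for s in STAGE2_STATES
        for i in range(4)
        if succ[s, i, 0] >= 0
        for x in succ[s, i]
    }
    if reachable != set(OUTCOME_STATES):
        raise ConfigError("all 8 outcome states must be reachable from stage-2 actions")

    if not 0.0 <= config.reward_prob <= 1.0:
        raise ConfigError("reward_prob must lie in [0, 1]")
    return StateSpaceModel(
        succ=succ, token_idx=token_idx, avail=avail,
        reward_prob=float(config.reward_prob), config=config,
    )


def sample_block_schedule(
    config: TaskConfig, n_trials_target: int, rng: np.random.Generator
) -> list[BlockCondition]:
    """Sample a randomized block schedule covering >= ``n_trials_target`` trials.

    Low-uncertainty blocks are 3-5 trials, high-uncertainty 5-7; each block's
    uncertainty is drawn with probability ``config.p_low_uncertainty`` (0.6 by
    default, so that the shorter low-uncertainty blocks contribute the same
    expected number of trials) and complexity with ``p_low_complexity``.
    """
    if n_trials_target < 1:
        raise ValueError("n_trials_target must be >= 1")
    schedule: list[BlockCondition] = []
    total = 0
    while total < n_trials_target:
        unc = "low" if rng.random() < config.p_low_uncertainty else "high"
        comp = "low" if rng.random() < config.p_low_complexity else "high"
        lo, hi = config.block_length[unc]
        n = int(rng.integers(lo, hi + 1))
        schedule.append(
            BlockCondition(
                uncertainty=unc,
                complexity=comp,
                transition_prob=tuple(config.transition_probs[unc]),
                n_trials=n,
            )
        )
        total += n
    return schedule


def draw_token_values(rng: np.random.Generator, config: TaskConfig | None = None) -> np.ndarray:
    """Draw the (red, blue, silver) token values for one trial from U(1,10).

    Integers by default (values are displayed as whole cents); continuous if
    ``config.token_values_continuous``.
    """
    config = config or TaskConfig()
    hi = config.token_value_max
    if config.token_values_continuous:
        return rng.uniform(1.0, hi, size=3)
    return rng.integers(1, int(hi) + 1, size=3).astype(float)


def env_step(
    model: StateSpaceModel,
    block: BlockCondition,
    state: int,
    action: str,
    rng: np.random.Generator,
    token_values: np.ndarray | None = None,
) -> tuple[int, float]:
    """One environment transition: returns ``(next_state, reward)``.

    From the start or a stage-2 state the successor is drawn from the
    (state, action) pair with the block's transition probabilities and reward
    is 0.  If the successor is an outcome state, ``token_values`` must be
    given and the token's value is paid with probability ``reward_prob``.
    """
    c = COMPLEXITY_LEVELS.index(block.complexity)
    ai = ACTION_INDEX[action]
    if not model.avail[c, state, ai]:
        raise ValueError(
            f"action {action} not available in state {state} under {block.complexity} complexity"
        )
    pair = model.succ[state, ai]
    nxt = int(pair[0]) if rng.random() < block.transition_prob[0] else int(pair[1])
    reward = 0.0
    if nxt in OUTCOME_STATES:
        if token_values is None:
            raise ValueError("token_values required when transitioning to an outcome state")
        ti = int(model.token_idx[nxt])
        if ti != NONE_TOKEN_IDX and rng.random() < model.reward_prob:
            reward = float(token_values[ti])
    return nxt, reward
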