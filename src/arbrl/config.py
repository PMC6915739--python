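"""Task configuration: the generative two-stage MDP and its session layout.

The task is a two-stage Markov decision task: from a single start state the
agent makes one of two choices, lands in one of two second-stage states, makes
another choice, and lands in one of eight outcome states, each labelled with a
coloured token (red / blue / silver) or no token.  Token-to-money exchange
rates are redrawn every trial, state-transition probabilities and the number
of available second-stage choices vary in short blocks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

#: canonical action order; indices into every per-action array
ACTIONS: tuple[str, ...] = ("L1", "L2", "R1", "R2")
ACTION_INDEX: Mapping[str, int] = {a: i for i, a in enumerate(ACTIONS)}

#: token kinds carrying value, in the fixed tie-break order
TOKENS: tuple[str, ...] = ("red", "blue", "silver")
TOKEN_INDEX: Mapping[str, int] = {t: i for i, t in enumerate(TOKENS)}
NO_TOKEN = "none"

START_STATE = 1
STAGE2_STATES = (2, 3)
OUTCOME_STATES = tuple(range(4, 12))
N_STATES = 12  # ids 1..11; index 0 unused

UNCERTAINTY_LEVELS = ("low", "high")
COMPLEXITY_LEVELS = ("low", "high")

# Default wiring: stage-1 actions point at the two stage-2 states (in opposite
# order), each stage-2 action covers two adjacent outcome states with wrap-
# around overlap so all eight outcomes stay reachable from four actions.
_DEFAULT_WIRING: dict[int, dict[str, tuple[int, int]]] = {
    1: {"L1": (2, 3), "R1": (3, 2)},
    2: {"L1": (4, 5), "L2": (5, 6), "R1": (6, 7), "R2": (7, 4)},
    3: {"L1": (8, 9), "L2": (9, 10), "R1": (10, 11), "R2": (11, 8)},
}

# Asymmetric token map: the silver token is only reachable through the left
# stage-2 state, so a full-knowledge planner acquires a left bias on trials
# where silver carries the top value while staying balanced otherwise.
_DEFAULT_TOKEN_MAP: dict[int, str] = {
    4: "red", 5: "blue", 6: "silver", 7: "none",
    8: "red", 9: "blue", 10: "none", 11: "none",
}


@dataclass(frozen=True)
class TaskConfig:
    """Full specification of the generative task.

    Parameters mirror the experiment: ``reward_prob`` is the probability a
    visited outcome state pays its token value; ``transition_probs`` maps the
    uncertainty condition to the ordered successor-probability pair;
    ``block_length`` maps uncertainty to the inclusive range of block lengths;
    ``p_low_uncertainty`` is the per-block probability of drawing a
    low-uncertainty block (0.6 equalises the trial-level exposure of the four
    condition cells, since low-uncertainty blocks are shorter on average).
    """

    reward_prob: float = 0.8
    transition_probs: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"low": (0.9, 0.1), "high": (0.5, 0.5)}
    )
    block_length: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"low": (3, 5), "high": (5, 7)}
    )
    token_map: Mapping[int, str] = field(
        default_factory=lambda: dict(_DEFAULT_TOKEN_MAP)
    )
    wiring: Mapping[int, Mapping[str, tuple[int, int]]] = field(
        default_factory=lambda: {s: dict(d) for s, d in _DEFAULT_WIRING.items()}
    )
    low_complexity_actions: tuple[str, str] = ("L1", "R1")
    n_sessions: int = 5
    trials_per_session: int = 80
    p_low_uncertainty: float = 0.6
    p_low_complexity: float = 0.5
    token_values_continuous: bool = False  # U(1,10): integers by default
    token_value_max: float = 10.0

    @classmethod
    def pretraining(cls) -> "TaskConfig":
        """The pre-training session: 100 free trials, p=(0.5,0.5), all tokens
        worth 5 (single session, high uncertainty only)."""
        return cls(
            transition_probs={"low": (0.5, 0.5), "high": (0.5, 0.5)},
            n_sessions=1,
            trials_per_session=100,
            p_low_uncertainty=0.0,
        )

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["transition_probs"] = {k: list(v) for k, v in self.transition_probs.items()}
        d["block_length"] = {k: list(v) for k, v in self.block_length.items()}
        d["wiring"] = {
            s: {a: list(p) for a, p in acts.items()} for s, acts in self.wiring.items()
        }
        d["token_map"] = dict(self.token_map)
        d["low_complexity_actions"] = list(self.low_complexity_actions)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "TaskConfig":
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ConfigError("task config YAML must be a mapping")
        kwargs = {}
        fields = {f.name for f in dataclasses.fields(cls)}
        for key, val in raw.items():
            if key not in fields:
                raise ConfigError(f"unknown task config key: {key!r}")
            kwargs[key] = val
        if "transition_probs" in kwargs:
            kwargs["transition_probs"] = {
                k: tuple(v) for k, v in kwargs["transition_probs"].items()
            }
        if "block_length" in kwargs:
            kwargs["block_length"] = {
                k: tuple(v) for k, v in kwargs["block_length"].items()
            }
        if "wiring" in kwargs:
            kwargs["wiring"] = {
                int(s): {a: tuple(p) for a, p in acts.items()}
                for s, acts in kwargs["wiring"].items()
            }
        if "token_map" in kwargs:
            kwargs["token_map"] = {int(s): t for s, t in kwargs["token_map"].items()}
        if "low_complexity_actions" in kwargs:
            kwargs["low_complexity_actions"] = tuple(kwargs["low_complexity_actions"])
        return cls(**kwargs)


class ConfigError(ValueError):
    """Raised when a task or run configuration violates its contract."""
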