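"""The runnable arbitration agent: learners + arbitrator wired per variant.

The agent exposes the same trial protocol to the closed-loop simulator and to
the deterministic replay used for fitting: ``begin_trial`` fixes the trial's
goal context, plans the MB values and returns nothing; ``stage_probs`` gives
the softmax choice distribution at a state; ``end_trial`` applies all
learning (transition model, SARSA tables, reliabilities) and one Euler step
of the P_MB dynamics.  All choices within a trial therefore use the P_MB
value from the end of the previous trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .arbitration import (
    ArbParams,
    ArbState,
    TAU_MULTIPLIER,
    complexity_code,
    integrate_values,
    action_probabilities,
    transition_rate,
    update_pmb,
)
from .config import ACTIONS, COMPLEXITY_LEVELS
from .learners import ForwardLearner, SarsaLearner, goal_context
from .model_space import ModelVariantSpec
from .task_env import START_STATE, StateSpaceModel

#: maximum token value used to normalize |RPE| before reliability thresholding
RPE_NORM = 10.0


@dataclass
class TrialTrace:
    """Per-trial arbitration audit record."""

    p_mb: float          # value governing this trial's choices
    rel_mf: float        # reliabilities after this trial's updates
    rel_mb: float
    alpha: float
    beta: float
    goal: int
    logp1: float = np.nan
    logp2: float = np.nan


class ArbitrationAgent:
    """A single model variant instantiated with concrete parameters.

    ``pin_pmb`` freezes the control weight (1.0 = pure MB, 0.0 = pure MF) and
    disables the arbitration dynamics; ``z_override`` forces the complexity
    code to a constant, which reduces any Interaction2 variant to the
    uncertainty-only baseline when set to 1.
    """

    def __init__(
        self,
        model: StateSpaceModel,
        spec: ModelVariantSpec,
        params: Mapping[str, float],
        p_mb_init: float = 0.5,
        pin_pmb: float | None = None,
        z_override: int | None = None,
    ):
        self.model = model
        self.spec = spec
        self.params = dict(params)
        self.p_mb_init = p_mb_init
        self.pin_pmb = pin_pmb
        self.z_override = z_override

        # ArbParams validates the arbitrator's parameter signs/ranges
        self.arb_params = ArbParams(
            A_mf2mb=self.params["A_mf2mb"], A_mb2mf=self.params["A_mb2mf"],
            B=self.params["B"], tau_base=self.params["tau_base"],
            c=self.params.get("c", 0.0),
        )
        etas = tuple(self.params[n] for n in spec.mf_param_names)
        self.mb = ForwardLearner(model, eta_mb=self.params["eta_mb"])
        self.mf = SarsaLearner(mf_type=spec.mf_type, etas=etas)
        self.arb = ArbState(p_mb=p_mb_init)

        self._mod_alpha = spec.interaction != "Null" and spec.direction in (
            "bidirectional", "mf2mb")
        self._mod_beta = spec.interaction != "Null" and spec.direction in (
            "bidirectional", "mb2mf")

        # per-trial context
        self._goal: int = 0
        self._comp: int = 0
        self._q_mb: np.ndarray | None = None
        self._tau: float = self.params["tau_base"]
        self.trace: list[TrialTrace] = []

    # -- session / trial protocol ------------------------------------------
    def reset_session(self) -> None:
        self.mb.reset()
        self.mf.reset()
        self.arb.reset(self.p_mb_init)
        self.trace = []

    @property
    def p_mb(self) -> float:
        return self.pin_pmb if self.pin_pmb is not None else self.arb.p_mb

    def begin_trial(
        self, token_values: np.ndarray, complexity: str,
        transition_prob: tuple[float, float] | None = None,
    ) -> None:
        # transition_prob is part of the shared agent protocol; the arbitration
        # agent never sees the true transition probabilities.
        self._goal = goal_context(token_values)
        self._comp = COMPLEXITY_LEVELS.index(complexity)
        self._q_mb = self.mb.plan(token_values, complexity)
        mult = TAU_MULTIPLIER[self.spec.exploration][self._comp]
        self._tau = self.params["tau_base"] * mult

    def stage_probs(self, state: int) -> tuple[np.ndarray, np.ndarray]:
        """(available action indices, choice probabilities) at ``state``."""
        avail = np.flatnonzero(self.model.avail[self._comp, state])
        q_mb = self._q_mb[state, avail]
        q_mf = self.mf.values(self._goal, state)[avail]
        q = integrate_values(q_mb, q_mf, self.p_mb)
        return avail, action_probabilities(q, self._tau)

    def sample_action(self, state: int, rng: np.random.Generator) -> int:
        avail, probs = self.stage_probs(state)
        return int(rng.choice(avail, p=probs))

    def end_trial(
        self, a1: int, s2: int, a2: int, s_out: int, reward: float,
        logp1: float = np.nan, logp2: float = np.nan,
    ) -> TrialTrace:
        """Apply all learning for the completed trial (action args are indices)."""
        p_mb_used = self.p_mb
        spe1 = self.mb.observe(START_STATE, a1, s2)
        self.arb.rel_mb_estimator.update(spe1)
        spe2 = self.mb.observe(s2, a2, s_out)
        self.arb.rel_mb_estimator.update(spe2)

        rpe1 = self.mf.update(self._goal, START_STATE, a1, 0.0, s2, a2)
        self.arb.rel_mf_estimator.update(abs(rpe1) / RPE_NORM)
        rpe2 = self.mf.update(self._goal, s2, a2, reward)
        self.arb.rel_mf_estimator.update(abs(rpe2) / RPE_NORM)

        alpha, beta = self.transition_rates()
        if self.pin_pmb is None:
            self.arb.p_mb = update_pmb(self.arb.p_mb, alpha, beta, dt=1.0)
        row = TrialTrace(
            p_mb=p_mb_used, rel_mf=self.arb.rel_mf, rel_mb=self.arb.rel_mb,
            alpha=alpha, beta=beta, goal=self._goal, logp1=logp1, logp2=logp2,
        )
        self.trace.append(row)
        return row

    def transition_rates(self) -> tuple[float, float]:
        """Current (alpha, beta) given the reliabilities, complexity and variant."""
        p = self.params
        z = (self.z_override if self.z_override is not None
             else complexity_code(self._comp, self.spec.sign)
             if self.spec.interaction != "Null" else 1)
        c = p.get("c", 0.0)
        if self._mod_alpha:
            alpha = transition_rate(self.arb.rel_mf, z, self.spec.interaction,
                                    p["A_mf2mb"], p["B"], c)
        else:
            alpha = transition_rate(self.arb.rel_mf, 1, "Null", p["A_mf2mb"], p["B"])
        if self._mod_beta:
            beta = transition_rate(self.arb.rel_mb, z, self.spec.interaction,
                                   p["A_mb2mf"], p["B"], c)
        else:
            beta = transition_rate(self.arb.rel_mb, 1, "Null", p["A_mb2mf"], p["B"])
        return alpha, beta

    def trace_frame(self):
        import pandas as pd

        return pd.DataFrame([vars(t) for t in self.trace])
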