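"""Closed-loop cohort simulation and deterministic replay.

Agents (arbitration variants, pure MB/MF, uniform, ideal) are run through
the generative task to produce complete behavioral datasets; the same agents
can be replayed deterministically on a recorded trial sequence, which is how
model-derived per-trial quantities (choice probabilities, P_MB) are obtained
for a fitted subject.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .agent import ArbitrationAgent
from .behavior_metrics import ideal_q
from .config import ACTIONS, ACTION_INDEX, TaskConfig
from .dataset import BehavioralDataset, TrialRecord
from .learners import goal_context
from .model_space import ModelVariantSpec, instantiate
from .task_env import (
    BlockCondition,
    START_STATE,
    StateSpaceModel,
    build_state_space,
    draw_token_values,
    env_step,
    sample_block_schedule,
)

#: generative sampling ranges for reference cohorts.  These are deliberately
#: narrower than the fitting bounds: they cover the logistic's sensitive
#: range (B of order 1-10 against reliabilities in [0,1]) and softmax
#: temperatures that produce stochastic but value-driven choices, i.e. the
#: regime fitted subjects occupy.
GENERATIVE_RANGES: Mapping[str, tuple[float, float]] = {
    "eta": (0.05, 0.8),
    "A": (0.1, 1.0),
    "B": (1.0, 10.0),
    "c": (-2.0, 2.0),
    "tau_base": (0.1, 1.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """A synthetic cohort: who is simulated and at what scale.

    Defaults mirror the study scale (24 subjects, 5 sessions x 80 trials).
    ``params`` fixes one generative parameter set for every subject; if None,
    each subject's parameters are drawn from ``GENERATIVE_RANGES``.
    Per-subject seeds are spawned deterministically from ``master_seed``.
    """

    variant_id: str = "best"
    n_subjects: int = 24
    n_sessions: int = 5
    trials_per_session: int = 80
    params: Mapping[str, float] | None = None
    master_seed: int = 0
    pin_pmb: float | None = None


def sample_generative_params(
    spec: ModelVariantSpec, rng: np.random.Generator,
    ranges: Mapping[str, tuple[float, float]] | None = None,
) -> dict[str, float]:
    """Draw one generative parameter set uniformly within the sampling ranges."""
    r = dict(GENERATIVE_RANGES)
    if ranges:
        r.update(ranges)
    out = {}
    for name in spec.param_names:
        key = ("eta" if name.startswith("eta") else
               "A" if name.startswith("A_") else
               "B" if name == "B" else
               "c" if name == "c" else "tau_base")
        lo, hi = r[key]
        out[name] = float(rng.uniform(lo, hi))
    return out


def simulate_subject(
    agent,
    config: TaskConfig,
    subject_id: str,
    rng: np.random.Generator,
    n_sessions: int | None = None,
    trials_per_session: int | None = None,
    model: StateSpaceModel | None = None,
) -> tuple[BehavioralDataset, pd.DataFrame]:
    """Run one agent through the task; returns (dataset, arbitration trace).

    The agent samples actions from its choice distribution, the environment
    returns transitions and rewards, and the agent learns; sessions reset the
    agent's state.
    """
    model = model or build_state_space(config)
    n_sessions = n_sessions or config.n_sessions
    trials_per_session = trials_per_session or config.trials_per_session
    records: list[TrialRecord] = []
    traces: list[pd.DataFrame] = []
    for session in range(1, n_sessions + 1):
        agent.reset_session()
        schedule = sample_block_schedule(config, trials_per_session, rng)
        trial = 0
        for block in schedule:
            for _ in range(block.n_trials):
                trial += 1
                tokens = draw_token_values(rng, config)
                agent.begin_trial(tokens, block.complexity, block.transition_prob)
                a1 = agent.sample_action(START_STATE, rng)
                s2, _ = env_step(model, block, START_STATE, ACTIONS[a1], rng)
                a2 = agent.sample_action(s2, rng)
                s_out, reward = env_step(model, block, s2, ACTIONS[a2], rng, tokens)
                agent.end_trial(a1, s2, a2, s_out, reward)
                records.append(TrialRecord(
                    subject=subject_id, session=session, trial=trial,
                    uncertainty=block.uncertainty, complexity=block.complexity,
                    p1=block.transition_prob[0],
                    token_values=tuple(map(float, tokens)),
                    s1=START_STATE, a1=ACTIONS[a1], s2=s2, a2=ACTIONS[a2],
                    s_out=s_out, reward=reward,
                    avail1=model.available_actions(START_STATE, block.complexity),
                    avail2=model.available_actions(s2, block.complexity),
                ))
        tr = agent.trace_frame()
        tr["session"] = session
        traces.append(tr)
    trace = pd.concat(traces, ignore_index=True)
    trace["subject"] = subject_id
    return BehavioralDataset.from_records(records), trace


def replay_subject(agent: ArbitrationAgent, dataset: BehavioralDataset) -> pd.DataFrame:
    """Deterministic replay: the agent experiences the recorded token values,
    conditions, transitions and rewards, and its own choice probabilities
    (plus argmax choices and P_MB) are recorded per trial."""
    rows = []
    for sess in dataset.iter_sessions():
        agent.reset_session()
        for rec in sess.itertuples(index=False):
            tokens = np.array([rec.token_red, rec.token_blue, rec.token_silver])
            agent.begin_trial(tokens, rec.complexity,
                              (rec.p1, round(1.0 - rec.p1, 12)))
            avail1, p1 = agent.stage_probs(START_STATE)
            a1 = ACTION_INDEX[rec.a1]
            prob1 = float(p1[list(avail1).index(a1)])
            argmax1 = int(avail1[int(np.argmax(p1))])
            avail2, p2 = agent.stage_probs(int(rec.s2))
            a2 = ACTION_INDEX[rec.a2]
            prob2 = float(p2[list(avail2).index(a2)])
            argmax2 = int(avail2[int(np.argmax(p2))])
            p_mb_used = agent.p_mb
            agent.end_trial(a1, int(rec.s2), a2, int(rec.s_out), float(rec.reward),
                            logp1=np.log(prob1), logp2=np.log(prob2))
            rows.append({
                "subject": rec.subject, "session": rec.session, "trial": rec.trial,
                "uncertainty": rec.uncertainty, "complexity": rec.complexity,
                "prob_a1": prob1, "prob_a2": prob2,
                "argmax_a1": ACTIONS[argmax1], "argmax_a2": ACTIONS[argmax2],
                "p_mb": p_mb_used,
            })
    return pd.DataFrame(rows)


class UniformAgent:
    """Chance agent: equal probability over the available actions."""

    def __init__(self, model: StateSpaceModel):
        self.model = model
        self._comp = 0
        self.trace: list = []

    def reset_session(self) -> None:
        self.trace = []

    def begin_trial(self, token_values, complexity, transition_prob=None) -> None:
        self._comp = 0 if complexity == "low" else 1

    def stage_probs(self, state: int):
        avail = np.flatnonzero(self.model.avail[self._comp, state])
        return avail, np.full(len(avail), 1.0 / len(avail))

    def sample_action(self, state: int, rng: np.random.Generator) -> int:
        avail, probs = self.stage_probs(state)
        return int(rng.choice(avail, p=probs))

    def end_trial(self, *args, **kwargs) -> None:
        self.trace.append({})

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(index=range(len(self.trace)))


class IdealAgentPolicy:
    """Argmax of the true-model optimal values (full knowledge, no learning)."""

    def __init__(self, model: StateSpaceModel):
        self.model = model
        self._q = None
        self._comp = 0
        self.trace: list = []

    def reset_session(self) -> None:
        self.trace = []

    def begin_trial(self, token_values, complexity, transition_prob) -> None:
        self._comp = 0 if complexity == "low" else 1
        block = BlockCondition(
            uncertainty="low", complexity=complexity,
            transition_prob=tuple(transition_prob), n_trials=1,
        )
        self._q = ideal_q(self.model, block, np.asarray(token_values, float))

    def stage_probs(self, state: int):
        avail = np.flatnonzero(self.model.avail[self._comp, state])
        q = self._q[state, avail]
        probs = np.where(q == np.max(q), 1.0, 0.0)
        return avail, probs / probs.sum()

    def sample_action(self, state: int, rng: np.random.Generator) -> int:
        avail, probs = self.stage_probs(state)
        return int(rng.choice(avail, p=probs))

    def end_trial(self, *args, **kwargs) -> None:
        self.trace.append({})

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(index=range(len(self.trace)))


#: representative parameters for the pure reference agents
REFERENCE_PARAMS = {
    "eta_mb": 0.2, "eta_mf": 0.2, "A_mf2mb": 0.5, "A_mb2mf": 0.5,
    "B": 5.0, "tau_base": 1.0,
}


def make_reference_agents(
    config: TaskConfig | None = None, model: StateSpaceModel | None = None,
    params: Mapping[str, float] | None = None,
) -> dict[str, object]:
    """The four reference agents: pure MB (P_MB pinned at 1), pure MF
    (pinned at 0), uniform-random, and the ideal full-knowledge agent."""
    model = model or build_state_space(config)
    p = dict(REFERENCE_PARAMS)
    if params:
        p.update(params)
    baseline = ModelVariantSpec.from_id("lee2014")
    return {
        "pure_MB": instantiate(baseline, p, model=model, pin_pmb=1.0),
        "pure_MF": instantiate(baseline, p, model=model, pin_pmb=0.0),
        "uniform": UniformAgent(model),
        "ideal": IdealAgentPolicy(model),
    }


def simulate_cohort(
    cohort: CohortSpec,
    config: TaskConfig | None = None,
    model: StateSpaceModel | None = None,
) -> tuple[BehavioralDataset, pd.DataFrame, dict]:
    """Simulate a full cohort; returns (dataset, traces, ground-truth sidecar).

    The sidecar records the generative variant, per-subject parameters and
    seeds, and is the reference for recovery analyses.
    """
    config = config or TaskConfig()
    model = model or build_state_space(config)
    spec = ModelVariantSpec.from_id(cohort.variant_id)
    seed_seq = np.random.SeedSequence(cohort.master_seed)
    children = seed_seq.spawn(cohort.n_subjects)
    datasets, traces = [], []
    sidecar = {
        "variant_id": spec.variant_id, "master_seed": cohort.master_seed,
        "n_sessions": cohort.n_sessions,
        "trials_per_session": cohort.trials_per_session,
        "subjects": {},
    }
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        subject = f"sim{i:03d}"
        params = (dict(cohort.params) if cohort.params is not None
                  else sample_generative_params(spec, rng))
        agent = instantiate(spec, params, model=model, pin_pmb=cohort.pin_pmb)
        ds, tr = simulate_subject(
            agent, config, subject, rng,
            n_sessions=cohort.n_sessions,
            trials_per_session=cohort.trials_per_session,
            model=model,
        )
        datasets.append(ds.df)
        traces.append(tr)
        sidecar["subjects"][subject] = {
            "params": params, "seed_entropy": int(child.entropy),
        }
    dataset = BehavioralDataset(pd.concat(datasets, ignore_index=True))
    return dataset, pd.concat(traces, ignore_index=True), sidecar


def write_cohort(
    out_dir: str | Path, dataset: BehavioralDataset, sidecar: dict,
    name: str = "cohort",
) -> tuple[Path, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / f"{name}.csv"
    side_path = out / f"{name}.truth.json"
    dataset.to_csv(csv_path)
    side_path.write_text(json.dumps(sidecar, indent=2))
    return csv_path, side_path
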