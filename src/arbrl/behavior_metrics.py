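"""Behavioral statistics: choice optimality, bias, consistency, switching,
and the condition-effect GLM with effect recovery.

Choice optimality scores each choice by the ideal agent's normalized value of
the chosen action, where the ideal agent plans with the *true* block
transition probabilities and full task knowledge.  The stage-2 score is
doubled in high-complexity blocks so a uniform-random agent has the same
chance baseline (0.5) in both complexity conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import ACTION_INDEX, ACTIONS, TOKENS
from .dataset import BehavioralDataset
from .learners import goal_context
from .task_env import BlockCondition, START_STATE, StateSpaceModel

LEFT_ACTIONS = {"L1", "L2"}

CELLS = [("low", "low"), ("low", "high"), ("high", "low"), ("high", "high")]


def ideal_q(
    model: StateSpaceModel,
    block: BlockCondition,
    token_values: np.ndarray,
) -> np.ndarray:
    """Optimal action values under the true generative model (full knowledge,
    no learning): exact backward induction with the block's transition
    probabilities and the task's reward probability."""
    from .learners import plan_q

    T_true = np.where(model.succ[:, :, 0] >= 0, block.transition_prob[0], np.nan)
    return plan_q(model, T_true, token_values, block.complexity, model.reward_prob)


def _block_of(row: pd.Series) -> BlockCondition:
    return BlockCondition(
        uncertainty=row["uncertainty"], complexity=row["complexity"],
        transition_prob=(row["p1"], round(1.0 - row["p1"], 12)), n_trials=1,
    )


def _normalized_value(qs: np.ndarray, avail: list[str], chosen: str) -> float | None:
    idx = [ACTION_INDEX[a] for a in avail]
    total = float(np.nansum(qs[idx]))
    if total <= 0:
        return None  # all-zero ideal values: trial carries no signal
    return float(qs[ACTION_INDEX[chosen]]) / total


def choice_optimality(
    dataset: BehavioralDataset,
    model: StateSpaceModel,
    stages: str = "both",
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-trial choice optimality and its per-subject condition summary.

    Per stage, the score is the ideal agent's value of the chosen action
    normalized over the available actions; the stage-2 score is multiplied by
    2 in high-complexity blocks (4 options instead of 2), which equalizes the
    random-choice baseline at 0.5 across complexity conditions.  ``stages``
    is ``"both"`` (mean of the two stages), ``"stage1"`` or ``"stage2"``.
    Trials where every available ideal value is zero are excluded (NaN).
    """
    df = dataset.df
    values = np.full(len(df), np.nan)
    for i, row in enumerate(df.itertuples(index=False)):
        if row.timeout:
            continue
        block = BlockCondition(
            uncertainty=row.uncertainty, complexity=row.complexity,
            transition_prob=(row.p1, round(1.0 - row.p1, 12)), n_trials=1,
        )
        tokens = np.array([row.token_red, row.token_blue, row.token_silver])
        q = ideal_q(model, block, tokens)
        parts = []
        if stages in ("both", "stage1"):
            v1 = _normalized_value(q[START_STATE], row.avail1.split("|"), row.a1)
            if v1 is not None:
                parts.append(v1)
        if stages in ("both", "stage2"):
            v2 = _normalized_value(q[row.s2], row.avail2.split("|"), row.a2)
            if v2 is not None:
                if row.complexity == "high":
                    v2 *= 2.0
                parts.append(v2)
        if parts:
            values[i] = float(np.mean(parts))
    per_trial = pd.Series(values, index=df.index, name="choice_optimality")
    return per_trial, condition_summary(df, per_trial)


def condition_summary(df: pd.DataFrame, per_trial: pd.Series) -> pd.DataFrame:
    """Per-subject means of a per-trial statistic in each of the four
    (uncertainty x complexity) cells, plus group mean and SEM rows."""
    tmp = df[["subject", "uncertainty", "complexity"]].copy()
    tmp["value"] = per_trial.to_numpy()
    per_subj = (
        tmp.dropna(subset=["value"])
        .groupby(["subject", "uncertainty", "complexity"])["value"]
        .agg(["mean", "count"])
        .reset_index()
    )
    group = (
        per_subj.groupby(["uncertainty", "complexity"])["mean"]
        .agg(group_mean="mean", group_sem="sem", n_subjects="count")
        .reset_index()
    )
    return per_subj.merge(group, on=["uncertainty", "complexity"])


def _goal_condition(df: pd.DataFrame) -> pd.Series:
    tok = df[["token_red", "token_blue", "token_silver"]].to_numpy(float)
    return pd.Series([TOKENS[goal_context(t)] for t in tok], index=df.index)


def choice_bias(dataset: BehavioralDataset) -> pd.DataFrame:
    """Stage-1 left-minus-right choice proportion per goal condition.

    Goal conditions bin trials by which token carries the maximum value; with
    the default asymmetric token map the silver goal is reachable only
    through the left stage-2 state, so a planner shows a left bias there.
    """
    df = dataset.df[dataset.df["timeout"] == 0].copy()
    df["goal_condition"] = _goal_condition(df)
    df["left"] = df["a1"].isin(LEFT_ACTIONS).astype(float)
    rows = []
    for (subj, goal), grp in df.groupby(["subject", "goal_condition"]):
        p_left = grp["left"].mean()
        rows.append({
            "subject": subj, "goal_condition": goal, "n_trials": len(grp),
            "bias": p_left - (1.0 - p_left),
        })
    return pd.DataFrame(rows)


def choice_consistency(dataset: BehavioralDataset) -> pd.DataFrame:
    """Probability of repeating the previous trial's stage-1 choice, per goal
    condition, computed within session."""
    df = dataset.df[dataset.df["timeout"] == 0].copy()
    df["goal_condition"] = _goal_condition(df)
    rows = []
    for subj, sdf in df.groupby("subject"):
        rec: dict[str, list[int]] = {t: [] for t in TOKENS}
        for _, sess in sdf.groupby("session"):
            a1 = sess["a1"].to_numpy()
            goals = sess["goal_condition"].to_numpy()
            for k in range(1, len(a1)):
                rec[goals[k]].append(int(a1[k] == a1[k - 1]))
        for goal, hits in rec.items():
            if hits:
                rows.append({
                    "subject": subj, "goal_condition": goal,
                    "n_trials": len(hits), "consistency": float(np.mean(hits)),
                })
    return pd.DataFrame(rows)


def switching_after_goal_change(
    dataset: BehavioralDataset, model: StateSpaceModel | None = None
) -> pd.DataFrame:
    """P(stage-1 switch | goal change) vs P(switch | no change) per subject.

    If ``model`` is given, also reports the switch-to-better rate: switches
    whose new choice has the higher ideal value on the new trial.
    """
    rows = []
    for subj, sdf in dataset.df[dataset.df["timeout"] == 0].groupby("subject"):
        counts = {0: [], 1: []}
        better = {0: [], 1: []}
        for _, sess in sdf.groupby("session"):
            recs = list(sess.itertuples(index=False))
            for prev, cur in zip(recs[:-1], recs[1:]):
                tok_prev = np.array([prev.token_red, prev.token_blue, prev.token_silver])
                tok_cur = np.array([cur.token_red, cur.token_blue, cur.token_silver])
                changed = int(goal_context(tok_cur) != goal_context(tok_prev))
                switched = int(cur.a1 != prev.a1)
                counts[changed].append(switched)
                if model is not None and switched:
                    block = _block_of(pd.Series(cur._asdict()))
                    q = ideal_q(model, block, tok_cur)[START_STATE]
                    better[changed].append(
                        int(q[ACTION_INDEX[cur.a1]] > q[ACTION_INDEX[prev.a1]])
                    )
        row = {
            "subject": subj,
            "p_switch_given_change": float(np.mean(counts[1])) if counts[1] else np.nan,
            "p_switch_given_no_change": float(np.mean(counts[0])) if counts[0] else np.nan,
            "n_change": len(counts[1]), "n_no_change": len(counts[0]),
        }
        if model is not None:
            row["p_switch_to_better_given_change"] = (
                float(np.mean(better[1])) if better[1] else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


GLM_REGRESSORS = ("uncertainty", "complexity", "reward_value", "prev_choice", "goal_value")


def effect_glm(
    dataset: BehavioralDataset,
    model: StateSpaceModel,
    per_trial_optimality: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject OLS of choice optimality on task regressors.

    Regressors (standardized within subject): uncertainty (high=1),
    complexity (high=1), reward_value (mean token value of the trial),
    prev_choice (previous stage-1 choice was left), goal_value (maximum token
    value).  Returns (per-subject standardized coefficients, group-level
    one-sample t-tests).  Rank-deficient designs are flagged and the
    offending coefficients dropped (NaN).
    """
    import statsmodels.api as sm

    if per_trial_optimality is None:
        per_trial_optimality, _ = choice_optimality(dataset, model)
    df = dataset.df.copy()
    df["_y"] = per_trial_optimality.to_numpy()
    rows = []
    for subj, sdf in df.groupby("subject"):
        sdf = sdf.copy()
        tok = sdf[["token_red", "token_blue", "token_silver"]].to_numpy(float)
        sdf["x_uncertainty"] = (sdf["uncertainty"] == "high").astype(float)
        sdf["x_complexity"] = (sdf["complexity"] == "high").astype(float)
        sdf["x_reward_value"] = tok.mean(axis=1)
        sdf["x_goal_value"] = tok.max(axis=1)
        prev_left = (
            sdf.groupby("session")["a1"]
            .transform(lambda s: s.isin(LEFT_ACTIONS).astype(float).shift())
        )
        sdf["x_prev_choice"] = prev_left
        sdf = sdf.dropna(subset=["_y", "x_prev_choice"])
        X = sdf[[f"x_{r}" for r in GLM_REGRESSORS]].to_numpy(float)
        y = sdf["_y"].to_numpy(float)
        sd = X.std(axis=0)
        keep = sd > 0
        Xz = np.zeros_like(X)
        Xz[:, keep] = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
        rank_ok = np.linalg.matrix_rank(Xz[:, keep]) == int(keep.sum())
        if not rank_ok:
            # drop later columns that duplicate earlier ones
            cols = []
            for j in np.flatnonzero(keep):
                trial_cols = cols + [j]
                if np.linalg.matrix_rank(Xz[:, trial_cols]) == len(trial_cols):
                    cols.append(j)
            keep = np.zeros(X.shape[1], dtype=bool)
            keep[cols] = True
        yz = (y - y.mean()) / (y.std() if y.std() > 0 else 1.0)
        res = sm.OLS(yz, sm.add_constant(Xz[:, keep])).fit()
        coefs = dict.fromkeys(GLM_REGRESSORS, np.nan)
        for j, name in zip(res.params[1:], np.array(GLM_REGRESSORS)[keep]):
            coefs[name] = float(j)
        rows.append({"subject": subj, "rank_deficient": not rank_ok, **coefs})
    per_subject = pd.DataFrame(rows)
    group_rows = []
    for name in GLM_REGRESSORS:
        vals = per_subject[name].dropna().to_numpy()
        if len(vals) >= 2:
            t, p = stats.ttest_1samp(vals, 0.0)
        else:
            t, p = np.nan, np.nan
        group_rows.append({
            "regressor": name, "mean_effect": float(np.mean(vals)) if len(vals) else np.nan,
            "t": float(t), "p": float(p), "n": len(vals),
        })
    return per_subject, pd.DataFrame(group_rows)


def effect_recovery(
    true_effects: pd.DataFrame, simulated_effects: pd.DataFrame,
    regressors: tuple[str, ...] = ("uncertainty", "complexity"),
) -> pd.DataFrame:
    """Across-subject correlation between effect sizes estimated from data
    and from the fitted model replayed on the same trial sequences."""
    merged = true_effects.merge(
        simulated_effects, on="subject", suffixes=("_true", "_sim")
    )
    rows = []
    for name in regressors:
        a = merged[f"{name}_true"].to_numpy(float)
        b = merged[f"{name}_sim"].to_numpy(float)
        ok = np.isfinite(a) & np.isfinite(b)
        r, p = stats.pearsonr(a[ok], b[ok]) if ok.sum() >= 3 else (np.nan, np.nan)
        rows.append({"regressor": name, "r": float(r), "p": float(p), "n": int(ok.sum())})
    return pd.DataFrame(rows)
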