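import numpy as np
import pandas as pd
import pytest

from arbrl.behavior_metrics import (
    choice_bias,
    choice_consistency,
    choice_optimality,
    effect_glm,
    effect_recovery,
    ideal_q,
    switching_after_goal_change,
)
from arbrl.config import ACTIONS, ACTION_INDEX
from arbrl.dataset import BehavioralDataset
from arbrl.synthetic_data import (
    CohortSpec,
    make_reference_agents,
    simulate_cohort,
    simulate_subject,
)
from arbrl.task_env import BlockCondition

from _oracles import brute_force_q


def _block(unc="low", comp="low"):
    p = (0.9, 0.1) if unc == "low" else (0.5, 0.5)
    return BlockCondition(unc, comp, p, 5)


class TestIdealQ:
    def test_stage2_closed_form_low_uncertainty(self, model):
        tokens = np.array([9.0, 4.0, 2.0])
        q = ideal_q(model, _block("low"), tokens)
        for s in (2, 3):
            for a_name in model.available_actions(s, "low"):
                a = ACTION_INDEX[a_name]
                o1, o2 = model.succ[s, a]
                v = [0.0 if model.token_idx[o] == 3 else tokens[model.token_idx[o]]
                     for o in (o1, o2)]
                assert q[s, a] == pytest.approx(0.8 * (0.9 * v[0] + 0.1 * v[1]))

    def test_max_entropy_symmetry(self, model):
        # under p=(0.5,0.5) the successor order is irrelevant
        tokens = np.array([3.0, 8.0, 5.0])
        q = ideal_q(model, _block("high", "high"), tokens)
        for s in (2, 3):
            for a in range(4):
                o1, o2 = model.succ[s, a]
                v = [0.0 if model.token_idx[o] == 3 else tokens[model.token_idx[o]]
                     for o in (o1, o2)]
                assert q[s, a] == pytest.approx(0.8 * 0.5 * (v[0] + v[1]))

    def test_equal_tokens_equalize_stage1(self, config):
        import dataclasses
        from arbrl.task_env import build_state_space

        model = build_state_space(dataclasses.replace(config, reward_prob=1.0))
        q = ideal_q(model, _block("high"), np.array([5.0, 5.0, 5.0]))
        # both stage-2 states offer a token on every low-complexity action pair
        assert np.isfinite(q[1, [0, 2]]).all()

    @pytest.mark.parametrize("unc,comp", [("low", "low"), ("high", "high")])
    def test_matches_brute_force(self, model, unc, comp):
        rng = np.random.default_rng(0)
        tokens = rng.uniform(1, 10, 3)
        block = _block(unc, comp)
        T_true = np.where(model.succ[:, :, 0] >= 0, block.transition_prob[0], np.nan)
        got = ideal_q(model, block, tokens)
        want = brute_force_q(model, T_true, tokens, comp, model.reward_prob)
        mask = np.isfinite(want)
        assert np.allclose(got[mask], want[mask], atol=1e-10)


class TestChoiceOptimality:
    @pytest.fixture(scope="class")
    def uniform_cohort(self, config, model):
        rng = np.random.default_rng(10)
        agents = make_reference_agents(config, model)
        ds, _ = simulate_subject(agents["uniform"], config, "uni", rng,
                                 n_sessions=4, trials_per_session=80, model=model)
        return ds

    def test_uniform_agent_expected_score_is_half_in_both_cells(self, model,
                                                                uniform_cohort):
        # analytic: a uniform chooser's expected corrected score per stage is
        # correction / n_available = 1/2 exactly, in every trial
        df = uniform_cohort.df
        for row in df.head(50).itertuples(index=False):
            block = _block(row.uncertainty, row.complexity)
            tokens = np.array([row.token_red, row.token_blue, row.token_silver])
            q = ideal_q(model, block, tokens)
            for state, avail in ((1, row.avail1), (row.s2, row.avail2)):
                names = avail.split("|")
                idx = [ACTION_INDEX[a] for a in names]
                tot = q[state, idx].sum()
                if tot <= 0:
                    continue
                corr = 2.0 if (row.complexity == "high" and state != 1) else 1.0
                expected = sum(corr * q[state, i] / tot for i in idx) / len(idx)
                assert expected == pytest.approx(0.5)

    def test_uniform_agent_means_near_chance(self, model, uniform_cohort):
        per_trial, summary = choice_optimality(uniform_cohort, model)
        for comp in ("low", "high"):
            cell = per_trial[uniform_cohort.df["complexity"] == comp]
            assert cell.mean() == pytest.approx(0.5, abs=0.05)

    def test_argmax_choice_on_equal_pair_scores_half(self, model, smoke_dataset):
        dataset, _, _ = smoke_dataset
        row = dataset.df.iloc[[0]].copy()
        row["uncertainty"], row["p1"] = "high", 0.5
        row["complexity"] = "low"
        row["s2"], row["avail2"] = 3, "L1|R1"
        row["a2"], row["s_out"], row["reward"] = "L1", 8, 0.0
        # state 3 under p=(0.5,0.5): L1 covers (8,9)=red/blue; R1 covers
        # (10,11)=none/none; choosing red/blue side with equal top tokens
        row["token_red"], row["token_blue"], row["token_silver"] = 5.0, 5.0, 1.0
        per_trial, _ = choice_optimality(BehavioralDataset(row), model,
                                         stages="stage2")
        assert per_trial.iloc[0] == pytest.approx(1.0)  # all value on L1 side

    def test_pure_mb_beats_pure_mf_per_cell(self, config, model):
        means = {}
        for name in ("pure_MB", "pure_MF"):
            cells = []
            for run in range(8):
                agents = make_reference_agents(config, model)
                rng = np.random.default_rng(100 + run)
                ds, _ = simulate_subject(agents[name], config, name, rng,
                                         n_sessions=2, trials_per_session=80,
                                         model=model)
                per_trial, _ = choice_optimality(ds, model)
                cells.append(per_trial.groupby(
                    [ds.df["uncertainty"], ds.df["complexity"]]).mean())
            means[name] = pd.concat(cells, axis=1).mean(axis=1)
        for cell in means["pure_MB"].index:
            assert means["pure_MB"][cell] > means["pure_MF"][cell], cell


class TestBiasConsistencySwitching:
    def _dataset_with_choices(self, model, a1_seq, tokens=None, n=None):
        n = n or len(a1_seq)
        rows = []
        rng = np.random.default_rng(0)
        for i in range(n):
            tok = tokens[i] if tokens is not None else rng.integers(1, 11, 3)
            a1 = a1_seq[i % len(a1_seq)]
            s2 = model.successors(1, a1)[0]
            a2 = "L1"
            s_out = model.successors(s2, a2)[0]
            rows.append({
                "subject": "s1", "session": 1, "trial": i + 1,
                "uncertainty": "low", "complexity": "low", "p1": 0.9,
                "token_red": tok[0], "token_blue": tok[1], "token_silver": tok[2],
                "s1": 1, "a1": a1, "s2": s2, "a2": a2, "s_out": s_out,
                "reward": 0.0, "avail1": "L1|R1", "avail2": "L1|R1", "timeout": 0,
            })
        return BehavioralDataset(pd.DataFrame(rows))

    def test_always_left_bias_and_consistency(self, model):
        ds = self._dataset_with_choices(model, ["L1"], n=60)
        assert (choice_bias(ds)["bias"] == 1.0).all()
        assert (choice_consistency(ds)["consistency"] == 1.0).all()

    def test_coin_flip_agent_balanced(self, config, model):
        rng = np.random.default_rng(12)
        agents = make_reference_agents(config, model)
        ds, _ = simulate_subject(agents["uniform"], config, "u", rng,
                                 n_sessions=4, trials_per_session=80, model=model)
        bias = choice_bias(ds)
        # ~107 trials/condition: 3 SE of a proportion difference ~ 0.29
        assert np.all(np.abs(bias["bias"]) < 0.3)
        cons = choice_consistency(ds)
        assert np.all(np.abs(cons["consistency"] - 0.5) < 0.15)

    def test_pure_mb_left_bias_under_silver_goal(self, config, model):
        rng = np.random.default_rng(13)
        agents = make_reference_agents(config, model)
        ds, _ = simulate_subject(agents["pure_MB"], config, "mb", rng,
                                 n_sessions=5, trials_per_session=80, model=model)
        bias = choice_bias(ds).set_index("goal_condition")["bias"]
        # silver is reachable only through the left stage-2 state, so the
        # planner's left bias concentrates in the silver-goal condition
        assert bias["silver"] > max(bias["red"], bias["blue"])
        assert bias["silver"] > 0.1
        assert bias.mean() > 0.0  # net left bias across goal conditions

    def test_perseverative_agent_consistency(self, model):
        rng = np.random.default_rng(14)
        seq = ["L1"]
        for _ in range(400):
            prev = seq[-1]
            seq.append(prev if rng.random() < 0.8
                       else ("R1" if prev == "L1" else "L1"))
        ds = self._dataset_with_choices(model, seq)
        cons = choice_consistency(ds)
        overall = (cons["consistency"] * cons["n_trials"]).sum() / cons["n_trials"].sum()
        se = np.sqrt(0.8 * 0.2 / 400)
        assert abs(overall - 0.8) < 3 * se

    def test_goal_blind_agent_switches_independently(self, config, model):
        rng = np.random.default_rng(15)
        agents = make_reference_agents(config, model)
        ds, _ = simulate_subject(agents["uniform"], config, "u", rng,
                                 n_sessions=4, trials_per_session=80, model=model)
        sw = switching_after_goal_change(ds).iloc[0]
        assert abs(sw["p_switch_given_change"] - sw["p_switch_given_no_change"]) < 0.15

    def test_pure_mb_switches_more_after_goal_change(self, config, model):
        rng = np.random.default_rng(16)
        agents = make_reference_agents(config, model)
        ds, _ = simulate_subject(agents["pure_MB"], config, "mb", rng,
                                 n_sessions=5, trials_per_session=80, model=model)
        sw = switching_after_goal_change(ds, model).iloc[0]
        assert sw["p_switch_given_change"] > sw["p_switch_given_no_change"]
        assert np.isfinite(sw["p_switch_to_better_given_change"])

    def test_no_goal_changes_reported_missing(self, model):
        tokens = [np.array([9, 1, 1])] * 30
        ds = self._dataset_with_choices(model, ["L1", "R1"], tokens=tokens)
        sw = switching_after_goal_change(ds).iloc[0]
        assert np.isnan(sw["p_switch_given_change"]) and sw["n_change"] == 0


class TestEffectGLM:
    @pytest.fixture(scope="class")
    def glm_cohort(self, config, model):
        cohort = CohortSpec(variant_id="lee2014", n_subjects=4, n_sessions=2,
                            trials_per_session=60, master_seed=17)
        dataset, _, _ = simulate_cohort(cohort, config, model)
        return dataset

    def test_pure_noise_gives_null_effects(self, model, glm_cohort):
        rng = np.random.default_rng(18)
        noise = pd.Series(rng.normal(size=len(glm_cohort.df)),
                          index=glm_cohort.df.index)
        per_subj, group = effect_glm(glm_cohort, model, per_trial_optimality=noise)
        assert np.all(np.abs(group["mean_effect"].to_numpy()) < 0.2)

    def test_planted_complexity_effect_recovered(self, model, glm_cohort):
        rng = np.random.default_rng(19)
        comp = (glm_cohort.df["complexity"] == "high").astype(float)
        y = 0.5 * comp + rng.normal(0, 1e-3, len(comp))
        per_subj, _ = effect_glm(glm_cohort, model,
                                 per_trial_optimality=pd.Series(y, index=glm_cohort.df.index))
        # standardized coefficient of a dominant binary regressor -> ~1
        assert np.all(per_subj["complexity"] > 0.9)
        assert np.all(np.abs(per_subj["uncertainty"]) < 0.1)

    def test_duplicated_regressor_flagged(self, model, glm_cohort):
        # equal token values make goal_value == reward_value -> rank deficiency
        df = glm_cohort.df.copy()
        vals = np.tile(df["token_red"].to_numpy(), (3, 1)).T
        df[["token_red", "token_blue", "token_silver"]] = np.clip(vals, 1, 10)
        ds = BehavioralDataset(df)
        rng = np.random.default_rng(20)
        noise = pd.Series(rng.normal(size=len(df)), index=df.index)
        per_subj, _ = effect_glm(ds, model, per_trial_optimality=noise)
        assert per_subj["rank_deficient"].all()
        assert per_subj["goal_value"].isna().all()


class TestEffectRecovery:
    def test_identity_and_permutation(self):
        rng = np.random.default_rng(21)
        true = pd.DataFrame({
            "subject": [f"s{i}" for i in range(30)],
            "uncertainty": rng.normal(size=30), "complexity": rng.normal(size=30),
        })
        sim = true.copy()
        out = effect_recovery(true, sim)
        assert np.allclose(out["r"], 1.0)
        perm = true.copy()
        perm[["uncertainty", "complexity"]] = (
            perm[["uncertainty", "complexity"]].sample(frac=1, random_state=0)
            .to_numpy())
        out_perm = effect_recovery(true, perm)
        assert np.all(np.abs(out_perm["r"]) < 0.5)
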