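"""Independent oracles used by the test suite.

These deliberately avoid the package's own planning / likelihood / BMS code
paths: exhaustive path enumeration for planning values, a hand-rolled trial
loop for the sequence likelihood of the baseline variant, and the conjugate
closed form for single-subject Bayesian model selection.
"""

import math

import numpy as np
from scipy import stats

from arbrl.config import ACTIONS, ACTION_INDEX


def brute_force_q(model, T_first, token_values, complexity, reward_prob):
    """Planning values by explicit enumeration of every path through the tree."""
    c = 0 if complexity == "low" else 1
    tok4 = list(token_values) + [0.0]

    def outcome_value(o):
        ti = model.token_idx[o]
        return 0.0 if ti == 3 else tok4[ti] * reward_prob

    def stage2_q(s, a):
        pair = model.succ[s, a]
        p = T_first[s, a]
        return sum(
            prob * outcome_value(int(o)) for prob, o in zip((p, 1 - p), pair)
        )

    q = np.full((12, 4), np.nan)
    for s in (2, 3):
        for a in range(4):
            if model.succ[s, a, 0] >= 0:
                q[s, a] = stage2_q(s, a)
    for a in range(4):
        if model.succ[1, a, 0] < 0:
            continue
        p = T_first[1, a]
        total = 0.0
        for prob, s2 in zip((p, 1 - p), model.succ[1, a]):
            best = max(
                q[int(s2), b]
                for b in range(4)
                if model.avail[c, int(s2), b]
            )
            total += prob * best
        q[1, a] = total
    return q


def naive_baseline_loglik(model, df, params):
    """Hand-rolled likelihood loop for the 1MF/Null/no-exploration variant.

    Written with dictionaries and explicit loops, independent of both the
    package's agent and its compiled kernel.
    """
    eta_mb, eta_mf = params["eta_mb"], params["eta_mf"]
    A_a, A_b, B, tau = params["A_mf2mb"], params["A_mb2mf"], params["B"], params["tau_base"]
    T = {}
    Q = {}
    mb_events, mf_events = [], []
    p_mb = 0.5
    logps = []

    def t_get(s, a):
        return T.setdefault((s, a), 0.5)

    def q_get(s, a):
        return Q.setdefault((s, a), 0.0)

    def avail(state, comp):
        c = 0 if comp == "low" else 1
        return [a for a in range(4) if model.avail[c, state, a]]

    def rel(events):
        window = events[-10:]
        return (sum(window) + 1.0) / (len(window) + 2.0)

    for row in df.itertuples(index=False):
        tokens = [row.token_red, row.token_blue, row.token_silver]
        # plan under current T
        def out_val(o):
            ti = model.token_idx[o]
            return 0.0 if ti == 3 else tokens[ti] * model.reward_prob

        q2 = {}
        for s in (2, 3):
            for a in avail(s, row.complexity):
                pair = model.succ[s, a]
                p = t_get(s, a)
                q2[(s, a)] = p * out_val(int(pair[0])) + (1 - p) * out_val(int(pair[1]))
        best2 = {s: max(v for (ss, _), v in q2.items() if ss == s) for s in (2, 3)}
        probs_logp = []
        for state, act in ((1, row.a1), (int(row.s2), row.a2)):
            acts = avail(state, row.complexity)
            qint = {}
            for a in acts:
                if state == 1:
                    pair = model.succ[1, a]
                    p = t_get(1, a)
                    qmb = p * best2[int(pair[0])] + (1 - p) * best2[int(pair[1])]
                else:
                    qmb = q2[(state, a)]
                qint[a] = p_mb * qmb + (1 - p_mb) * q_get(state, a)
            denom = sum(math.exp(tau * v) for v in qint.values())
            probs_logp.append(math.log(math.exp(tau * qint[ACTION_INDEX[act]]) / denom))
        logps.append(probs_logp)

        # learn
        for (s, a, nxt) in ((1, ACTION_INDEX[row.a1], int(row.s2)),
                            (int(row.s2), ACTION_INDEX[row.a2], int(row.s_out))):
            pair = model.succ[s, a]
            p_obs = t_get(s, a) if nxt == pair[0] else 1 - t_get(s, a)
            spe = 1 - p_obs
            if nxt == pair[0]:
                T[(s, a)] = t_get(s, a) + eta_mb * spe
            else:
                T[(s, a)] = t_get(s, a) - eta_mb * spe
            mb_events.append(1 if spe <= 0.3 else 0)
        a1, a2 = ACTION_INDEX[row.a1], ACTION_INDEX[row.a2]
        rpe1 = q_get(int(row.s2), a2) - q_get(1, a1)
        Q[(1, a1)] = q_get(1, a1) + eta_mf * rpe1
        mf_events.append(1 if abs(rpe1) / 10.0 <= 0.1 else 0)
        rpe2 = row.reward - q_get(int(row.s2), a2)
        Q[(int(row.s2), a2)] = q_get(int(row.s2), a2) + eta_mf * rpe2
        mf_events.append(1 if abs(rpe2) / 10.0 <= 0.1 else 0)

        alpha = A_a / (1 + math.exp(B * rel(mf_events)))
        beta = A_b / (1 + math.exp(B * rel(mb_events)))
        p_mb = min(1.0, max(0.0, p_mb + alpha * (1 - p_mb) - beta * p_mb))
    return np.array(logps)


def conjugate_bms_exceedance(log_ev):
    """Exact single-subject, two-model exceedance under a Dirichlet(1,1) prior.

    The posterior over frequencies is the mixture sum_m w_m Dir(1 + e_m) with
    w_m proportional to the model evidences; P(r1 > r2) under Dir(2,1) is
    1 - CDF_Beta(2,1)(1/2) = 0.75.
    """
    e = np.exp(log_ev - np.max(log_ev))
    w = e / e.sum()
    p_given_1 = 1.0 - stats.beta(2, 1).cdf(0.5)   # component Dir(2,1)
    p_given_2 = 1.0 - stats.beta(1, 2).cdf(0.5)   # component Dir(1,2)
    return w[0] * p_given_1 + w[1] * p_given_2
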