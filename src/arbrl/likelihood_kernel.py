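"""Compiled trial-replay likelihood for fitting.

This kernel replays a recorded trial sequence under a model variant and
returns the log-probability of each recorded choice.  It mirrors
:class:`arbrl.agent.ArbitrationAgent` operation for operation (the test suite
asserts agreement between the two paths); it exists because maximum-
likelihood fitting of ~100 subject-variant pairs needs the per-evaluation
cost to be microseconds, not milliseconds.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .agent import RPE_NORM
from .arbitration import (
    RELIABILITY_WINDOW,
    RPE_RELIABILITY_THRESHOLD,
    SPE_RELIABILITY_THRESHOLD,
)
from .model_space import ModelVariantSpec
from .task_env import StateSpaceModel, START_STATE

# integer codes for variant factors
MF_CODE = {"1MF": 0, "3Q": 1, "3MF": 2}
INTER_CODE = {"Null": 0, "Interaction1": 1, "Interaction2": 2}
SIGN_CODE = {None: 0, "excitatory": 0, "inhibitory": 1}
DIR_CODE = {None: 0, "bidirectional": 0, "mb2mf": 1, "mf2mb": 2}
EXP_CODE = {"null": 0, "explorative": 1, "exploitative": 2}


def variant_codes(spec: ModelVariantSpec) -> tuple[int, int, int, int, int]:
    return (MF_CODE[spec.mf_type], INTER_CODE[spec.interaction],
            SIGN_CODE[spec.sign], DIR_CODE[spec.direction],
            EXP_CODE[spec.exploration])


def pack_params(spec: ModelVariantSpec, params: dict[str, float]) -> np.ndarray:
    """Canonical kernel parameter layout:
    [eta_mb, eta_red, eta_blue, eta_silver, A_mf2mb, A_mb2mf, B, c, tau_base]
    (the three MF rates are duplicated for 1MF/3Q; c is 0 unless fitted)."""
    if spec.mf_type == "3MF":
        e = (params["eta_mf_red"], params["eta_mf_blue"], params["eta_mf_silver"])
    else:
        e = (params["eta_mf"],) * 3
    return np.array(
        [params["eta_mb"], *e, params["A_mf2mb"], params["A_mb2mf"],
         params["B"], params.get("c", 0.0), params["tau_base"]],
        dtype=np.float64,
    )


@njit(cache=True)
def _rate(x, z, modulated, inter_code, A, B, c):
    if modulated and inter_code == 1:
        u = B * (1.0 + c * z) * x
        amp = A
    elif modulated and inter_code == 2:
        u = B * x
        amp = A * z
    else:
        u = B * x
        amp = A
    return amp / (1.0 + math.exp(min(u, 700.0)))


@njit(cache=True)
def _replay(
    theta,
    mf_code, inter_code, sign_code, dir_code, exp_code,
    pin_pmb,        # <0: free dynamics; else P_MB pinned at this value
    z_override,     # 0: none; else forced z for modulated directions
    reward_prob,
    succ, token_idx, avail,
    new_session, complexity, tokens, a1, s2, a2, s_out, reward,
    logp_out, pmb_out,
):
    n = a1.shape[0]
    eta_mb = theta[0]
    A_a, A_b, B, c, tau_base = theta[4], theta[5], theta[6], theta[7], theta[8]
    mod_alpha = inter_code != 0 and (dir_code == 0 or dir_code == 2)
    mod_beta = inter_code != 0 and (dir_code == 0 or dir_code == 1)

    T = np.full((12, 4), 0.5)
    QMF = np.zeros((3, 12, 4))
    mb_buf = np.zeros(RELIABILITY_WINDOW, dtype=np.int64)
    mf_buf = np.zeros(RELIABILITY_WINDOW, dtype=np.int64)
    mb_n = 0
    mf_n = 0
    mb_i = 0
    mf_i = 0
    p_mb = 0.5
    q1 = np.zeros(4)
    q2 = np.zeros(4)
    probs = np.zeros(4)

    for t in range(n):
        if new_session[t]:
            T[:, :] = 0.5
            QMF[:, :, :] = 0.0
            mb_n = 0
            mf_n = 0
            mb_i = 0
            mf_i = 0
            p_mb = 0.5
        comp = complexity[t]
        # goal context: first maximum in (red, blue, silver) order
        g = 0
        if tokens[t, 1] > tokens[t, g]:
            g = 1
        if tokens[t, 2] > tokens[t, g]:
            g = 2
        table = 0 if mf_code == 0 else g
        eta_mf = theta[1 + g] if mf_code == 2 else theta[1]

        # --- MB planning (backward induction under T) ---
        best2_2 = -1.0e300
        best2_3 = -1.0e300
        for s in range(2, 4):
            for a in range(4):
                if succ[s, a, 0] < 0 or not avail[comp, s, a]:
                    continue
                v0 = 0.0
                v1 = 0.0
                ti0 = token_idx[succ[s, a, 0]]
                ti1 = token_idx[succ[s, a, 1]]
                if ti0 < 3:
                    v0 = tokens[t, ti0] * reward_prob
                if ti1 < 3:
                    v1 = tokens[t, ti1] * reward_prob
                q = T[s, a] * v0 + (1.0 - T[s, a]) * v1
                if s == 2:
                    if q > best2_2:
                        best2_2 = q
                else:
                    if q > best2_3:
                        best2_3 = q

        p_used = p_mb if pin_pmb < 0.0 else pin_pmb
        tau = tau_base
        if exp_code == 1:
            tau = tau_base * (1.0 if comp == 0 else 0.5)
        elif exp_code == 2:
            tau = tau_base * (0.5 if comp == 0 else 1.0)

        # --- stage 1 choice probability ---
        for a in range(4):
            q1[a] = -1.0e300
            if succ[1, a, 0] < 0 or not avail[comp, 1, a]:
                continue
            sA = succ[1, a, 0]
            sB = succ[1, a, 1]
            bA = best2_2 if sA == 2 else best2_3
            bB = best2_2 if sB == 2 else best2_3
            q_mb = T[1, a] * bA + (1.0 - T[1, a]) * bB
            q1[a] = p_used * q_mb + (1.0 - p_used) * QMF[table, 1, a]
        logp_out[t, 0] = _softmax_logp(q1, avail, comp, 1, tau, a1[t], probs)

        # --- stage 2 choice probability ---
        st2 = s2[t]
        for a in range(4):
            q2[a] = -1.0e300
            if succ[st2, a, 0] < 0 or not avail[comp, st2, a]:
                continue
            v0 = 0.0
            v1 = 0.0
            ti0 = token_idx[succ[st2, a, 0]]
            ti1 = token_idx[succ[st2, a, 1]]
            if ti0 < 3:
                v0 = tokens[t, ti0] * reward_prob
            if ti1 < 3:
                v1 = tokens[t, ti1] * reward_prob
            q_mb = T[st2, a] * v0 + (1.0 - T[st2, a]) * v1
            q2[a] = p_used * q_mb + (1.0 - p_used) * QMF[table, st2, a]
        logp_out[t, 1] = _softmax_logp(q2, avail, comp, st2, tau, a2[t], probs)

        # --- learning: SPEs ---
        for stage in range(2):
            if stage == 0:
                s = 1
                a = a1[t]
                nxt = st2
            else:
                s = st2
                a = a2[t]
                nxt = s_out[t]
            if nxt == succ[s, a, 0]:
                p_obs = T[s, a]
                spe = 1.0 - p_obs
                T[s, a] += eta_mb * spe
            else:
                p_obs = 1.0 - T[s, a]
                spe = 1.0 - p_obs
                T[s, a] -= eta_mb * spe
            mb_buf[mb_i] = 1 if spe <= SPE_RELIABILITY_THRESHOLD else 0
            mb_i = (mb_i + 1) % RELIABILITY_WINDOW
            if mb_n < RELIABILITY_WINDOW:
                mb_n += 1

        # --- learning: SARSA RPEs ---
        rpe1 = QMF[table, st2, a2[t]] - QMF[table, 1, a1[t]]
        QMF[table, 1, a1[t]] += eta_mf * rpe1
        mf_buf[mf_i] = 1 if abs(rpe1) / RPE_NORM <= RPE_RELIABILITY_THRESHOLD else 0
        mf_i = (mf_i + 1) % RELIABILITY_WINDOW
        if mf_n < RELIABILITY_WINDOW:
            mf_n += 1
        rpe2 = reward[t] - QMF[table, st2, a2[t]]
        QMF[table, st2, a2[t]] += eta_mf * rpe2
        mf_buf[mf_i] = 1 if abs(rpe2) / RPE_NORM <= RPE_RELIABILITY_THRESHOLD else 0
        mf_i = (mf_i + 1) % RELIABILITY_WINDOW
        if mf_n < RELIABILITY_WINDOW:
            mf_n += 1

        # --- arbitration step ---
        rel_mb = (_bufsum(mb_buf, mb_n) + 1.0) / (mb_n + 2.0)
        rel_mf = (_bufsum(mf_buf, mf_n) + 1.0) / (mf_n + 2.0)
        z = 1 + comp if sign_code == 0 else 2 - comp
        if z_override > 0:
            z = z_override
        alpha = _rate(rel_mf, z, mod_alpha, inter_code, A_a, B, c)
        beta = _rate(rel_mb, z, mod_beta, inter_code, A_b, B, c)
        if pin_pmb < 0.0:
            p_mb = p_mb + (alpha * (1.0 - p_mb) - beta * p_mb)
            p_mb = min(1.0, max(0.0, p_mb))
        pmb_out[t] = p_used


@njit(cache=True)
def _bufsum(buf, n):
    s = 0
    for i in range(n):
        s += buf[i]
    return s


@njit(cache=True)
def _softmax_logp(q, avail, comp, state, tau, chosen, probs):
    m = -1.0e300
    for a in range(4):
        if avail[comp, state, a] and tau * q[a] > m:
            m = tau * q[a]
    tot = 0.0
    for a in range(4):
        if avail[comp, state, a]:
            probs[a] = math.exp(tau * q[a] - m)
            tot += probs[a]
        else:
            probs[a] = 0.0
    return math.log(probs[chosen] / tot)


def replay_loglik(
    spec: ModelVariantSpec,
    params: dict[str, float] | np.ndarray,
    model: StateSpaceModel,
    arrays: dict[str, np.ndarray],
    pin_pmb: float | None = None,
    z_override: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-choice log-probabilities (n_trials, 2) and the per-trial P_MB used.

    ``params`` may be a name->value dict or an already-packed theta vector.
    """
    theta = params if isinstance(params, np.ndarray) else pack_params(spec, params)
    codes = variant_codes(spec)
    n = arrays["a1"].shape[0]
    logp = np.empty((n, 2))
    pmb = np.empty(n)
    _replay(
        theta, *codes,
        -1.0 if pin_pmb is None else float(pin_pmb),
        0 if z_override is None else int(z_override),
        model.reward_prob,
        model.succ, model.token_idx, model.avail,
        arrays["new_session"], arrays["complexity"], arrays["tokens"],
        arrays["a1"], arrays["s2"], arrays["a2"], arrays["s_out"],
        arrays["reward"],
        logp, pmb,
    )
    return logp, pmb
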