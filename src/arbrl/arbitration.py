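"""Dynamic arbitration between model-based and model-free control.

The arbitrator keeps a control weight ``P_MB`` (probability of allocating
control to the MB system) that evolves as a two-state dynamic system,

    dP_MB/dt = alpha (1 - P_MB) - beta P_MB,

with transition rates alpha (MF -> MB) and beta (MB -> MF) that are logistic
functions of the competing system's reliability, optionally modulated by task
complexity (the ``z`` code).  Action values of the two systems are mixed by
``P_MB`` and passed through a softmax whose inverse temperature may itself
depend on complexity.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

#: sliding-window length of the reliability estimator (prediction-error events)
RELIABILITY_WINDOW = 10
#: normalized |RPE| at or below this counts as a zero-error event for the MF
#: system
RPE_RELIABILITY_THRESHOLD = 0.1
#: SPE at or below this counts as a zero-error event for the MB system.  The
#: threshold sits between the asymptotic SPE of a learned low-uncertainty
#: transition (0.1 on the common successor of a (0.9, 0.1) pair) and the SPE
#: of a maximum-entropy (0.5, 0.5) transition, so MB reliability actually
#: discriminates the two uncertainty conditions.
SPE_RELIABILITY_THRESHOLD = 0.3
#: generic default for a standalone estimator
RELIABILITY_THRESHOLD = 0.1

TRANSITION_VARIANTS = ("Null", "Interaction1", "Interaction2")
SIGNS = ("excitatory", "inhibitory")
DIRECTIONS = ("bidirectional", "mb2mf", "mf2mb")
EXPLORATION_EFFECTS = ("null", "explorative", "exploitative")

#: tau(z) multipliers per (effect, complexity 0 low / 1 high)
TAU_MULTIPLIER = {
    "null": (1.0, 1.0),
    "explorative": (1.0, 0.5),
    "exploitative": (0.5, 1.0),
}


def complexity_code(complexity_high: int, sign: str) -> int:
    """The modulation level z: excitatory -> (1 low, 2 high); inhibitory ->
    (2 low, 1 high)."""
    if sign == "excitatory":
        return 1 + int(complexity_high)
    if sign == "inhibitory":
        return 2 - int(complexity_high)
    raise ValueError(f"unknown sign {sign!r}")


@dataclass
class ArbParams:
    """Free parameters of the arbitrator.

    ``A_mf2mb``/``A_mb2mf`` are the maximum transition rates of the two
    directions (per trial), ``B`` the shared logistic steepness, ``c`` the
    complexity-reliability interaction coefficient (Interaction1 only),
    ``tau_base`` the softmax inverse temperature (per value unit, i.e. per
    cent) scaled by the complexity multiplier.
    """

    A_mf2mb: float
    A_mb2mf: float
    B: float
    tau_base: float
    c: float = 0.0

    def __post_init__(self) -> None:
        if self.A_mf2mb <= 0 or self.A_mb2mf <= 0:
            raise ValueError("maximum transition rates A must be > 0")
        if self.B <= 0:
            raise ValueError("steepness B must be > 0")
        if self.tau_base <= 0:
            raise ValueError("tau_base must be > 0")


class ReliabilityEstimator:
    """Posterior-mean reliability from a sliding window of PE events.

    Each prediction error is discretized into zero / nonzero categories by a
    threshold on its magnitude (RPEs are first normalized by the maximum token
    value; SPEs already live in [0, 1]).  The reliability is the posterior
    mean probability of the zero-error category under a symmetric
    Dirichlet(1) prior: ``x = (n_zero + 1) / (n + 2)`` over the last
    ``window`` events, so an empty window gives the prior mean 1/2.
    """

    def __init__(self, window: int = RELIABILITY_WINDOW,
                 threshold: float = RELIABILITY_THRESHOLD):
        if threshold < 0:
            raise ValueError("threshold must be >= 0")
        self.window = window
        self.threshold = threshold
        self._events: deque[int] = deque(maxlen=window)

    def reset(self) -> None:
        self._events.clear()

    def update(self, pe_magnitude: float) -> float:
        """Append one |PE| event and return the updated reliability."""
        self._events.append(1 if pe_magnitude <= self.threshold else 0)
        return self.value

    @property
    def value(self) -> float:
        n = len(self._events)
        return (sum(self._events) + 1.0) / (n + 2.0)


def transition_rate(
    x: float,
    z: int,
    variant: str,
    A: float,
    B: float,
    c: float = 0.0,
) -> float:
    """Transition rate as a function of reliability ``x`` and complexity ``z``.

    Null:          A / (1 + exp(B x))
    Interaction1:  A / (1 + exp(B (1 + c z) x))   (direct z-x interaction)
    Interaction2:  A z / (1 + exp(B x))           (indirect, gain on A)
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError("reliability x must lie in [0, 1]")
    if variant == "Null":
        u = B * x
        amp = A
    elif variant == "Interaction1":
        u = B * (1.0 + c * z) * x
        amp = A
    elif variant == "Interaction2":
        u = B * x
        amp = A * z
    else:
        raise ValueError(f"unknown transition variant {variant!r}")
    # exp overflow guard; u can be large for B near its upper bound
    return amp / (1.0 + math.exp(min(u, 700.0)))


def update_pmb(p_mb: float, alpha: float, beta: float, dt: float = 1.0) -> float:
    """One forward-Euler step of the P_MB dynamics, clamped to [0, 1]."""
    if alpha < 0 or beta < 0:
        raise ValueError("transition rates must be >= 0")
    p = p_mb + dt * (alpha * (1.0 - p_mb) - beta * p_mb)
    return min(1.0, max(0.0, p))


def steady_state_pmb(alpha: float, beta: float) -> float:
    """Fixed point alpha / (alpha + beta) of the P_MB dynamics."""
    if alpha < 0 or beta < 0:
        raise ValueError("transition rates must be >= 0")
    if alpha + beta == 0:
        raise ValueError("steady state undefined for alpha = beta = 0")
    return alpha / (alpha + beta)


def integrate_values(q_mb: np.ndarray, q_mf: np.ndarray, p_mb: float) -> np.ndarray:
    """Weighted value integration Q = P_MB * Q_MB + (1 - P_MB) * Q_MF."""
    return p_mb * np.asarray(q_mb, float) + (1.0 - p_mb) * np.asarray(q_mf, float)


def action_probabilities(q: np.ndarray, tau: float) -> np.ndarray:
    """Overflow-safe softmax ``exp(tau q) / sum exp(tau q)`` over the given
    (already availability-restricted) action values."""
    q = np.asarray(q, float)
    if q.size < 1:
        raise ValueError("need at least one available action")
    u = tau * q
    u = u - u.max()
    e = np.exp(u)
    return e / e.sum()


@dataclass
class ArbState:
    """The arbitrator's evolving state over a session."""

    p_mb: float = 0.5
    rel_mf_estimator: ReliabilityEstimator = field(
        default_factory=lambda: ReliabilityEstimator(
            threshold=RPE_RELIABILITY_THRESHOLD))
    rel_mb_estimator: ReliabilityEstimator = field(
        default_factory=lambda: ReliabilityEstimator(
            threshold=SPE_RELIABILITY_THRESHOLD))

    @property
    def rel_mf(self) -> float:
        return self.rel_mf_estimator.value

    @property
    def rel_mb(self) -> float:
        return self.rel_mb_estimator.value

    def reset(self, p_mb_init: float = 0.5) -> None:
        self.p_mb = p_mb_init
        self.rel_mf_estimator.reset()
        self.rel_mb_estimator.reset()
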