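"""Adaptive gain scheduling for SPGD.

The gain coefficient is updated each iteration from the phase of the
optimization:

    gamma(k+1) = gamma(k) + alpha * (gamma0 - gamma(k)) + beta(k) * H(k)

    beta(k) = xi * |sign(DJ+(k)) - sign(DJ-(k))|
    H(k)    = |dJ(k)| * sum_{l=1..L} |J(k) - J(k-l)| * exp(-1 / (J0 - J(k)))

The contraction term alpha * (gamma0 - gamma) pulls the gain back to its
asymptote gamma0; the adaptation term beta * H boosts it while the metric is
still climbing.  beta vanishes when the one-sided metric changes DJ+ and DJ-
share a sign (both negative near an optimum) and equals 2*xi on a slope where
they disagree.  H grows with the current metric slope and with the distance
of J from the desired level J0, and vanishes once the metric has been
stationary for the last L iterations or has reached J0.

The scheduler needs L past baseline values before it can update, so the gain
first departs from its initial value at iteration L + 1 (iteration 6 with the
default window of 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .spgd_core import IterationRecord

__all__ = [
    "AdaptiveGainConfig",
    "GainState",
    "beta",
    "h_term",
    "gamma_update",
    "AdaptiveGainScheduler",
]


@dataclass(frozen=True)
class AdaptiveGainConfig:
    """Parameters of the gain law; defaults are the adaptive-mode settings
    (gamma0=4, alpha=0.9, xi=15, L=5, J0=10)."""

    gamma0: float = 4.0
    alpha: float = 0.9
    xi: float = 15.0
    history_window: int = 5
    J_target: float = 10.0
    gamma_init: Optional[float] = None  # defaults to gamma0
    gamma_min: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if self.xi < 0:
            raise ValueError("xi must be nonnegative")
        if self.history_window < 1:
            raise ValueError("history_window must be >= 1")
        if self.gamma0 <= 0:
            raise ValueError("gamma0 must be positive")

    @property
    def initial_gamma(self) -> float:
        return self.gamma0 if self.gamma_init is None else self.gamma_init


@dataclass
class GainState:
    """Current gain plus the recent baseline-metric history."""

    gamma_k: float
    J_history: list[float] = field(default_factory=list)
    k: int = 0


def beta(dJ_plus: float, dJ_minus: float, xi: float) -> float:
    """Sign-disagreement term xi * |sign(DJ+) - sign(DJ-)|, with sign(0) = 0."""
    return float(xi * abs(np.sign(dJ_plus) - np.sign(dJ_minus)))


def h_term(
    delta_J: float,
    J_current: float,
    J_history: list[float] | np.ndarray,
    J_target: float,
) -> float:
    """Phase-identification term H(k); always >= 0.

    Clamped to 0 when J_current >= J_target: the exponential factor
    exp(-1/(J0 - J)) tends to zero as J approaches J0 from below, and the
    clamp extends that limit continuously past the singularity at J = J0.
    """
    hist = np.asarray(J_history, dtype=float)
    if hist.size == 0:
        raise ValueError("J_history must be nonempty")
    if J_current >= J_target:
        return 0.0
    total_change = float(np.sum(np.abs(J_current - hist)))
    return abs(delta_J) * total_change * float(np.exp(-1.0 / (J_target - J_current)))


def gamma_update(
    state: GainState, beta_k: float, H_k: float, cfg: AdaptiveGainConfig
) -> GainState:
    """One application of the gain recursion, floored at cfg.gamma_min."""
    g = state.gamma_k + cfg.alpha * (cfg.gamma0 - state.gamma_k) + beta_k * H_k
    return GainState(gamma_k=max(g, cfg.gamma_min), J_history=list(state.J_history), k=state.k + 1)


class AdaptiveGainScheduler:
    """Stateful gain source for :func:`confocal_ao.spgd_core.run_spgd`.

    For the first ``history_window`` iterations the gain stays at its initial
    value while baseline metric values fill the history buffer; from then on
    every iteration's record triggers a gain update for the next iteration.
    During the very first update the buffer holds fewer than L entries and the
    history sum runs over what is available.
    """

    def __init__(self, cfg: AdaptiveGainConfig | None = None):
        self.cfg = cfg or AdaptiveGainConfig()
        self.state = GainState(gamma_k=self.cfg.initial_gamma)
        self.trace: list[tuple[int, float, float, float]] = []  # (k, beta, H, gamma_next)

    @property
    def current_gamma(self) -> float:
        return self.state.gamma_k

    def update(self, record: IterationRecord) -> float:
        """Consume iteration ``record`` and return the gain for the next iteration."""
        if record.k != self.state.k + 1:
            raise ValueError(
                f"records must arrive in order: expected k={self.state.k + 1}, got {record.k}"
            )
        if record.J_base is None or record.dJ_plus is None or record.dJ_minus is None:
            raise ValueError("adaptive gain requires baseline evaluations (J_base, DJ+/-)")
        L = self.cfg.history_window
        if record.k < L:
            # warm-up: collect baselines, keep gamma at its initial value
            self.state.J_history.append(record.J_base)
            self.state.k = record.k
            record.beta_k = 0.0
            record.H_k = 0.0
            self.trace.append((record.k, 0.0, 0.0, self.state.gamma_k))
            return self.state.gamma_k
        b = beta(record.dJ_plus, record.dJ_minus, self.cfg.xi)
        if self.state.J_history:
            H = h_term(record.delta_J, record.J_base, self.state.J_history, self.cfg.J_target)
        else:  # history_window == 1: no past baseline yet at the first update
            H = 0.0
        new = gamma_update(self.state, b, H, self.cfg)
        new.J_history = (self.state.J_history + [record.J_base])[-L:]
        new.k = record.k
        self.state = new
        record.beta_k = b
        record.H_k = H
        self.trace.append((record.k, b, H, new.gamma_k))
        return new.gamma_k
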