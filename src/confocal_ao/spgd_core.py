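"""Stochastic parallel gradient descent (SPGD) with bilateral perturbation.

Every iteration perturbs all actuators simultaneously with independent random
signs (Bernoulli +/- sigma), measures the metric at u + du and u - du, forms
the bilateral metric change dJ = [J(u+du) - J(u-du)] / 2 and ascends:

    u_j <- u_j + gamma * dJ * du_j

With positive gain gamma this climbs the metric; gamma may be fixed or
supplied per-iteration by an adaptive scheduler, in which case a baseline
evaluation J(u) is added so the scheduler can see the one-sided changes
DJ+ = J(u+du) - J(u) and DJ- = J(u-du) - J(u).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol

import numpy as np
import pandas as pd

from .deformable_mirror import ControlVector, clip

__all__ = [
    "SPGDConfig",
    "IterationRecord",
    "RunResult",
    "sample_perturbation",
    "bilateral_delta",
    "spgd_step",
    "run_spgd",
    "detect_plateau",
]


@dataclass(frozen=True)
class SPGDConfig:
    """Optimizer parameters.

    ``perturbation_amplitude`` is |du_j|, the per-actuator perturbation
    magnitude; ``gain`` is the fixed gain coefficient gamma (ignored when an
    adaptive scheduler is attached).  Defaults follow the fixed-coefficient
    settings |du| = 0.005, gamma = 5.
    """

    perturbation_amplitude: float = 0.005
    gain: float = 5.0
    max_iterations: int = 100
    seed: int = 0
    u_max: float = 1.0
    stop_on_plateau: bool = False

    def __post_init__(self) -> None:
        if self.perturbation_amplitude <= 0:
            raise ValueError("perturbation_amplitude must be positive")
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class IterationRecord:
    """Everything measured in one iteration; the raw data of a convergence curve."""

    k: int
    J_plus: float
    J_minus: float
    delta_J: float
    gamma_k: float
    J_base: Optional[float] = None
    dJ_plus: Optional[float] = None
    dJ_minus: Optional[float] = None
    beta_k: Optional[float] = None
    H_k: Optional[float] = None
    u_snapshot: Optional[np.ndarray] = None

    @property
    def J_estimate(self) -> float:
        """Best available estimate of J(u) this iteration."""
        return self.J_base if self.J_base is not None else 0.5 * (self.J_plus + self.J_minus)


@dataclass
class RunResult:
    records: list[IterationRecord]
    final_u: ControlVector
    converged: bool
    convergence_iteration: Optional[int]

    def metric_trace(self) -> np.ndarray:
        return np.array([r.J_estimate for r in self.records])

    def gain_trace(self) -> np.ndarray:
        return np.array([r.gamma_k for r in self.records])

    def to_dataframe(self) -> pd.DataFrame:
        cols = ["k", "J_base", "J_plus", "J_minus", "delta_J", "gamma_k", "beta_k", "H_k"]
        return pd.DataFrame(
            [{c: getattr(r, c) for c in cols} for r in self.records], columns=cols
        )

    def to_csv(self, path, controls_path=None) -> None:
        """One row per iteration; optionally the control snapshots (iteration x actuator)."""
        self.to_dataframe().to_csv(path, index=False)
        if controls_path is not None:
            snaps = [r.u_snapshot for r in self.records if r.u_snapshot is not None]
            pd.DataFrame(np.asarray(snaps)).to_csv(controls_path, index=False)


class GainSchedule(Protocol):
    """Per-iteration gain source for :func:`run_spgd`."""

    @property
    def current_gamma(self) -> float: ...

    def update(self, record: IterationRecord) -> float: ...


def sample_perturbation(
    n_actuators: int, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Independent +/-amplitude per actuator with probability 1/2 each."""
    if n_actuators < 1:
        raise ValueError("n_actuators must be >= 1")
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    signs = rng.integers(0, 2, size=n_actuators) * 2 - 1
    return amplitude * signs.astype(float)


def bilateral_delta(J_plus: float, J_minus: float) -> float:
    """dJ = [J(u+du) - J(u-du)] / 2."""
    if not (np.isfinite(J_plus) and np.isfinite(J_minus)):
        raise ValueError("metric values must be finite")
    return 0.5 * (J_plus - J_minus)


def spgd_step(
    u: ControlVector, delta_u: np.ndarray, delta_J: float, gamma: float
) -> ControlVector:
    """One ascent update u_j + gamma * dJ * du_j, clipped to the actuator bounds."""
    if delta_u.shape != u.u.shape:
        raise ValueError("perturbation length does not match control vector")
    return clip(ControlVector(u.u + gamma * delta_J * delta_u, u_max=u.u_max))


def detect_plateau(
    J_series: np.ndarray,
    window: int = 10,
    rel_tol: float = 0.01,
    streak: int = 10,
) -> Optional[int]:
    """Convergence iteration under the plateau rule, or None.

    The moving average of J over the last ``window`` iterations must change by
    less than ``rel_tol`` relative for ``streak`` consecutive iterations; the
    returned (1-based) iteration is the first of that streak.
    """
    J = np.asarray(J_series, dtype=float)
    if J.size < window + streak:
        return None
    kernel = np.ones(window) / window
    mov = np.convolve(J, kernel, mode="valid")  # mov[i] = mean of J[i:i+window]
    ok = np.abs(np.diff(mov)) < rel_tol * np.abs(mov[:-1])
    run = 0
    for i, flag in enumerate(ok):
        run = run + 1 if flag else 0
        if run >= streak:
            # ok[i] compares moving means ending at iterations window+i and window+i+1
            return int(window + i + 1 - streak + 1)
    return None


def run_spgd(
    objective: Callable[[ControlVector], float],
    n_actuators: int,
    cfg: SPGDConfig,
    gain_schedule: Optional[GainSchedule] = None,
    u0: Optional[ControlVector] = None,
    record_controls: bool = False,
) -> RunResult:
    """Run SPGD on ``objective`` (to be maximized), fully seeded.

    Fixed-gain mode spends 2 objective evaluations per iteration; with an
    adaptive ``gain_schedule`` a per-iteration baseline J(u) is added (3
    evaluations) because the scheduler needs the one-sided metric changes.
    """
    rng = np.random.default_rng(cfg.seed)
    u = u0.copy() if u0 is not None else ControlVector.zeros(n_actuators, u_max=cfg.u_max)

    def evaluate(v: ControlVector, k: int) -> float:
        val = float(objective(v))
        if not np.isfinite(val):
            raise RuntimeError(f"objective returned non-finite value at iteration {k}")
        return val

    records: list[IterationRecord] = []
    for k in range(1, cfg.max_iterations + 1):
        J_base = evaluate(u, k) if gain_schedule is not None else None
        du = sample_perturbation(n_actuators, cfg.perturbation_amplitude, rng)
        J_plus = evaluate(ControlVector(u.u + du, u_max=u.u_max), k)
        J_minus = evaluate(ControlVector(u.u - du, u_max=u.u_max), k)
        dJ = bilateral_delta(J_plus, J_minus)
        gamma_k = cfg.gain if gain_schedule is None else gain_schedule.current_gamma
        rec = IterationRecord(
            k=k,
            J_plus=J_plus,
            J_minus=J_minus,
            delta_J=dJ,
            gamma_k=gamma_k,
            J_base=J_base,
            dJ_plus=None if J_base is None else J_plus - J_base,
            dJ_minus=None if J_base is None else J_minus - J_base,
        )
        u = spgd_step(u, du, dJ, gamma_k)
        if record_controls:
            rec.u_snapshot = u.u.copy()
        if gain_schedule is not None:
            gain_schedule.update(rec)
        records.append(rec)
        if cfg.stop_on_plateau:
            conv = detect_plateau(np.array([r.J_estimate for r in records]))
            if conv is not None:
                break

    trace = np.array([r.J_estimate for r in records])
    conv = detect_plateau(trace)
    return RunResult(
        records=records,
        final_u=u,
        converged=conv is not None,
        convergence_iteration=conv,
    )
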