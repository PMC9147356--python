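"""Linear model of a 69-actuator continuous-membrane deformable mirror.

The mirror phase is a weighted sum of Gaussian influence functions, one per
actuator, scaled by ``stroke_gain`` radians of phase per unit command.  The
Gaussian width is set from the inter-actuator coupling: the influence function
of an actuator evaluated at its nearest neighbour equals ``coupling`` (15% by
default, a typical value for continuous-membrane mirrors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wavefront import PupilGrid, Wavefront

__all__ = [
    "ActuatorLayout",
    "ControlVector",
    "InfluenceModel",
    "default_layout_69",
    "influence_matrix",
    "mirror_phase",
    "clip",
]


@dataclass(frozen=True)
class ActuatorLayout:
    """Actuator positions in pupil-normalized coordinates (radius 1 = aperture edge)."""

    positions: np.ndarray  # (count, 2)
    pitch: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must have shape (count, 2)")
        object.__setattr__(self, "positions", pos)
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        r = np.hypot(pos[:, 0], pos[:, 1])
        if np.any(r > 1.1 + 1e-9):
            raise ValueError("all actuators must lie within 1.1x the aperture radius")

    @property
    def count(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class InfluenceModel:
    """Gaussian influence functions: value ``coupling`` at the nearest neighbour."""

    coupling: float = 0.15
    # 2.5 waves of phase per unit command (double pass absorbed); calibrated so
    # a 0.005 command perturbation drives paper-scale metric changes
    stroke_gain: float = 5.0 * np.pi

    def __post_init__(self) -> None:
        if not 0.0 < self.coupling < 1.0:
            raise ValueError("coupling must be in (0, 1)")
        if self.stroke_gain <= 0:
            raise ValueError("stroke_gain must be positive")


class ControlVector:
    """Per-actuator command values, clipped to [-u_max, u_max]."""

    __slots__ = ("u", "u_max", "saturated")

    def __init__(self, u: np.ndarray, u_max: float = 1.0, saturated: bool = False):
        self.u = np.asarray(u, dtype=float)
        if self.u.ndim != 1:
            raise ValueError("control vector must be one-dimensional")
        self.u_max = float(u_max)
        self.saturated = bool(saturated)

    def __len__(self) -> int:
        return self.u.size

    @classmethod
    def zeros(cls, count: int, u_max: float = 1.0) -> "ControlVector":
        return cls(np.zeros(count), u_max=u_max)

    def copy(self) -> "ControlVector":
        return ControlVector(self.u.copy(), u_max=self.u_max, saturated=self.saturated)


def default_layout_69(span: float = 0.95) -> ActuatorLayout:
    """9x9 square actuator grid with the three pixels of each corner removed.

    81 - 4*3 = 69 actuators, matching a 69-channel membrane mirror.  ``span``
    is the half-width of the grid in pupil-normalized coordinates; the default
    slightly oversizes the pupil so edge aberrations remain controllable, as
    is standard when mapping a membrane mirror onto a beam.
    """
    n = 9
    ax = np.linspace(-span, span, n)
    pitch = ax[1] - ax[0]
    xs, ys = np.meshgrid(ax, ax, indexing="xy")
    keep = []
    for i in range(n):
        for j in range(n):
            # L1 distance from the nearest corner in grid steps; < 2 removes the
            # corner and its two edge neighbours (3 per corner, 12 in total)
            if min(i, n - 1 - i) + min(j, n - 1 - j) < 2:
                continue
            keep.append((xs[i, j], ys[i, j]))
    pos = np.array(keep)
    assert pos.shape[0] == 69
    return ActuatorLayout(positions=pos, pitch=pitch)


def influence_matrix(
    layout: ActuatorLayout, model: InfluenceModel, grid: PupilGrid
) -> np.ndarray:
    """Influence functions sampled on the full grid: shape (count, n, n).

    Each row is stroke_gain * g_j with g_j(x) = exp(-|x - x_j|^2 / w^2) and
    w chosen so g_j(pitch) = coupling.
    """
    w2 = layout.pitch**2 / np.log(1.0 / model.coupling)
    x, y = grid.coords()
    n = grid.n_samples
    out = np.empty((layout.count, n, n))
    for j, (xj, yj) in enumerate(layout.positions):
        out[j] = model.stroke_gain * np.exp(-((x - xj) ** 2 + (y - yj) ** 2) / w2)
    return out


def mirror_phase(
    u: ControlVector,
    layout: ActuatorLayout,
    model: InfluenceModel,
    grid: PupilGrid,
    _matrix: np.ndarray | None = None,
) -> Wavefront:
    """Mirror-induced wavefront for command vector ``u`` (strictly linear in u).

    ``_matrix`` may carry a precomputed :func:`influence_matrix` to avoid
    re-evaluating the Gaussians inside optimization loops.
    """
    if len(u) != layout.count:
        raise ValueError(f"control vector length {len(u)} != actuator count {layout.count}")
    m = influence_matrix(layout, model, grid) if _matrix is None else _matrix
    phase = np.tensordot(u.u, m, axes=(0, 0))
    return Wavefront(phase, grid)


def clip(u: ControlVector, u_max: float | None = None) -> ControlVector:
    """Componentwise clamp to [-u_max, u_max]; sets the saturation flag if clamping occurred."""
    bound = u.u_max if u_max is None else float(u_max)
    if bound <= 0:
        raise ValueError("u_max must be positive")
    clipped = np.clip(u.u, -bound, bound)
    return ControlVector(clipped, u_max=bound, saturated=bool(np.any(clipped != u.u)))
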