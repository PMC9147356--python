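"""Zernike basis, wavefront composition and aberration generation on a sampled pupil.

Pupil-phase maps are represented as full 2-D arrays (radians) together with a
boolean aperture mask; values outside the mask are kept at zero and carry no
meaning.  Zernike modes follow the Noll single-index convention with Noll
normalization, so every non-piston mode has unit RMS over the continuous unit
disk (and, to discretization accuracy, over the sampled mask).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np

__all__ = [
    "PupilGrid",
    "Wavefront",
    "ZernikeSpec",
    "noll_to_nm",
    "zernike_mode",
    "compose_wavefront",
    "random_aberration",
    "rms_error",
]


@dataclass(frozen=True)
class PupilGrid:
    """Square sampling grid with a centred circular aperture.

    Parameters
    ----------
    n_samples:
        Side length of the grid in pixels.
    aperture_radius:
        Aperture radius in pixels.  Defaults to 0.45 * n_samples, which keeps
        the pupil fully inside the grid with a small guard band.
    """

    n_samples: int = 128
    aperture_radius: float | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 8:
            raise ValueError(f"n_samples must be >= 8, got {self.n_samples}")
        if self.aperture_radius is None:
            object.__setattr__(self, "aperture_radius", 0.45 * self.n_samples)
        if self.aperture_radius <= 0:
            raise ValueError("aperture_radius must be positive")

    @property
    def center(self) -> float:
        # (n-1)/2 keeps the mask point-symmetric about the grid centre
        return (self.n_samples - 1) / 2.0

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Pupil-normalized coordinates (x, y): radius 1 at the aperture edge."""
        c = self.center
        ax = (np.arange(self.n_samples) - c) / self.aperture_radius
        x, y = np.meshgrid(ax, ax, indexing="xy")
        return x, y

    def polar(self) -> tuple[np.ndarray, np.ndarray]:
        """Pupil-normalized polar coordinates (rho, theta)."""
        x, y = self.coords()
        return np.hypot(x, y), np.arctan2(y, x)

    @property
    def mask(self) -> np.ndarray:
        rho, _ = self.polar()
        return rho <= 1.0 + 1e-12

    @property
    def n_mask(self) -> int:
        return int(self.mask.sum())


@dataclass
class Wavefront:
    """Phase map in radians on a :class:`PupilGrid`; defined where the mask is true."""

    phase: np.ndarray
    grid: PupilGrid

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.shape != (self.grid.n_samples, self.grid.n_samples):
            raise ValueError(
                f"phase shape {self.phase.shape} does not match grid "
                f"({self.grid.n_samples}, {self.grid.n_samples})"
            )
        if not np.all(np.isfinite(self.phase[self.grid.mask])):
            raise ValueError("phase contains non-finite values inside the aperture")

    def __add__(self, other: "Wavefront") -> "Wavefront":
        if other.grid != self.grid:
            raise ValueError("cannot add wavefronts defined on different grids")
        return Wavefront(self.phase + other.phase, self.grid)

    def __mul__(self, scalar: float) -> "Wavefront":
        return Wavefront(self.phase * float(scalar), self.grid)

    __rmul__ = __mul__

    def in_mask(self) -> np.ndarray:
        """Phase values of the in-aperture pixels, as a flat array."""
        return self.phase[self.grid.mask]

    @classmethod
    def zero(cls, grid: PupilGrid) -> "Wavefront":
        return cls(np.zeros((grid.n_samples, grid.n_samples)), grid)

    def to_tiff(self, path) -> None:
        """Export the phase map as 32-bit float TIFF (radians)."""
        import tifffile

        tifffile.imwrite(path, self.phase.astype(np.float32))


@dataclass(frozen=True)
class ZernikeSpec:
    """A single Zernike term: Noll index plus coefficient in radians RMS."""

    index: int
    coefficient: float

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"Noll index must be >= 1, got {self.index}")


def noll_to_nm(j: int) -> tuple[int, int]:
    """Convert a Noll single index to (n, m) with the sign of m encoding sin/cos.

    Noll's rule: even j -> cosine (m >= 0), odd j -> sine (m < 0); within a
    radial order the |m| values are assigned in ascending order pairwise.
    """
    if j < 1:
        raise ValueError(f"Noll index must be >= 1, got {j}")
    n = 0
    j1 = j - 1
    while j1 > n:
        n += 1
        j1 -= n
    m_abs = (n % 2) + 2 * ((j1 + ((n + 1) % 2)) // 2)
    if m_abs == 0:
        return n, 0
    sign = 1 if j % 2 == 0 else -1
    return n, sign * m_abs


def _radial_poly(n: int, m_abs: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho)
    for k in range((n - m_abs) // 2 + 1):
        c = (-1) ** k * comb(n - k, k) * comb(n - 2 * k, (n - m_abs) // 2 - k)
        out += c * rho ** (n - 2 * k)
    return out


def zernike_mode(index: int, grid: PupilGrid) -> Wavefront:
    """Noll-normalized Zernike polynomial sampled on the grid.

    Modes with index >= 2 have unit RMS over the unit disk; piston (index 1)
    is the constant 1.
    """
    n, m = noll_to_nm(index)
    rho, theta = grid.polar()
    r = _radial_poly(n, abs(m), np.clip(rho, 0.0, 1.0))
    if m == 0:
        z = np.sqrt(n + 1.0) * r
    elif m > 0:
        z = np.sqrt(2.0 * (n + 1)) * r * np.cos(m * theta)
    else:
        z = np.sqrt(2.0 * (n + 1)) * r * np.sin(-m * theta)
    z = np.where(grid.mask, z, 0.0)
    return Wavefront(z, grid)


def compose_wavefront(specs: list[ZernikeSpec] | dict[int, float], grid: PupilGrid) -> Wavefront:
    """Weighted sum of Zernike modes; duplicate indices combine by summation."""
    if isinstance(specs, dict):
        specs = [ZernikeSpec(j, c) for j, c in specs.items()]
    coeffs: dict[int, float] = {}
    for s in specs:
        coeffs[s.index] = coeffs.get(s.index, 0.0) + s.coefficient
    phase = np.zeros((grid.n_samples, grid.n_samples))
    for j, c in coeffs.items():
        if c != 0.0:
            phase += c * zernike_mode(j, grid).phase
    return Wavefront(phase, grid)


def random_aberration(
    rms_target: float, max_index: int, seed: int, grid: PupilGrid
) -> Wavefront:
    """Random low-order Zernike mixture with exact in-mask RMS ``rms_target``.

    Coefficients are drawn for Noll indices 4..max_index (piston, tip and tilt
    excluded) with standard deviation proportional to 1/index, then the
    composed wavefront is rescaled so its piston-removed in-mask RMS equals
    ``rms_target``.  Reproducible for a fixed seed.
    """
    if rms_target <= 0:
        raise ValueError("rms_target must be positive")
    if max_index < 4:
        raise ValueError(f"max_index must be >= 4, got {max_index}")
    rng = np.random.default_rng(seed)
    indices = np.arange(4, max_index + 1)
    coeffs = rng.standard_normal(indices.size) / indices
    w = compose_wavefront({int(j): float(c) for j, c in zip(indices, coeffs)}, grid)
    current = rms_error(w)
    if current == 0.0:  # vanishingly unlikely; redraw deterministically
        return random_aberration(rms_target, max_index, seed + 1, grid)
    return w * (rms_target / current)


def rms_error(w: Wavefront) -> float:
    """Piston-removed RMS of the in-mask phase, in radians."""
    v = w.in_mask()
    return float(np.sqrt(np.mean((v - v.mean()) ** 2)))
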