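"""Fourier-optics forward model of a laser-scanning confocal microscope.

The pupil (aperture mask times exp(i*phase)) is zero-padded and Fourier
transformed to obtain the excitation intensity PSF.  Confocal detection
through a small pinhole is modelled as the pixelwise product of excitation
and detection PSFs; excitation and emission share one wavelength and one
wavefront (the Stokes shift and any non-common path are ignored).  Images are
formed by circular convolution of a fluorophore-density phantom with the
confocal PSF — exactly equivalent to a point-by-point scan for a
shift-invariant PSF — followed by Poisson photon noise and Gaussian read
noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft
from scipy import ndimage

from .wavefront import PupilGrid, Wavefront

__all__ = [
    "OpticalConfig",
    "Phantom",
    "NoiseModel",
    "psf_from_wavefront",
    "confocal_psf",
    "render_image",
    "reference_peak",
    "make_phantom",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Optical-system description.

    ``pad_factor`` controls PSF sampling: the pupil grid is zero-padded by
    this factor before the FFT, so the diffraction-limited Airy core spans
    several image pixels (>= 3 px FWHM at the default settings).
    """

    wavelength_nm: float = 488.0
    numerical_aperture: float = 0.65
    image_size: int = 128
    pad_factor: int = 4

    def __post_init__(self) -> None:
        if not 0.0 < self.numerical_aperture < 1.0:
            raise ValueError("numerical_aperture must be in (0, 1)")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength_nm must be positive")
        if self.pad_factor < 1:
            raise ValueError("pad_factor must be >= 1")

    def airy_radius_px(self, grid: PupilGrid) -> float:
        """First Airy zero in PSF pixels: 1.22 * N_fft / D_pupil."""
        n_fft = self.pad_factor * grid.n_samples
        return 1.22 * n_fft / (2.0 * grid.aperture_radius)

    def pixel_scale_nm(self, grid: PupilGrid) -> float:
        """Object-plane sampling: 0.61 lambda / NA mapped onto the Airy radius in pixels."""
        return (0.61 * self.wavelength_nm / self.numerical_aperture) / self.airy_radius_px(grid)


@dataclass(frozen=True)
class Phantom:
    """Nonnegative fluorophore density per pixel, peak-normalized on creation."""

    density: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.density, dtype=float)
        if d.ndim != 2:
            raise ValueError("phantom must be a 2-D array")
        if np.any(d < 0):
            raise ValueError("phantom density must be nonnegative")
        if not np.any(d > 0):
            raise ValueError("phantom must contain at least one positive pixel")
        object.__setattr__(self, "density", d)


@dataclass(frozen=True)
class NoiseModel:
    """Photon (Poisson) and read (Gaussian) noise of the detector chain."""

    photon_scale: float = 500.0  # expected peak photon count in the unaberrated image
    read_sigma: float = 2.0  # additive Gaussian sigma, photons
    seed: int = 0

    def __post_init__(self) -> None:
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be positive")
        if self.read_sigma < 0:
            raise ValueError("read_sigma must be nonnegative")


def _pupil_field(w: Wavefront, cfg: OpticalConfig) -> np.ndarray:
    grid = w.grid
    n = grid.n_samples
    n_fft = cfg.pad_factor * n
    field = np.zeros((n_fft, n_fft), dtype=complex)
    mask = grid.mask
    block = np.where(mask, np.exp(1j * w.phase), 0.0)
    lo = (n_fft - n) // 2
    field[lo : lo + n, lo : lo + n] = block
    return field


def psf_from_wavefront(w: Wavefront, cfg: OpticalConfig) -> np.ndarray:
    """Widefield intensity PSF on the padded grid, normalized to unit sum.

    The returned array has side ``pad_factor * n_samples``; the peak of the
    unaberrated PSF sits at its centre pixel.  Keeping the full grid (rather
    than cropping to the field of view) conserves energy: light scattered to
    large angles by a rough wavefront stays accounted for.
    """
    field = _pupil_field(w, cfg)
    amp = scipy.fft.fft2(scipy.fft.ifftshift(field))
    psf = np.abs(scipy.fft.fftshift(amp)) ** 2
    return psf / psf.sum()


def confocal_psf(w: Wavefront, cfg: OpticalConfig) -> np.ndarray:
    """Effective confocal PSF: product of excitation and detection PSFs, unit sum.

    Both passes see the same wavefront (double pass through the corrector
    path); the pinhole is treated as an ideal point detector.  Renormalizing
    the product to unit sum absorbs the overall confocal signal loss of an
    aberrated wavefront — the model's stand-in for detector-gain adjustment —
    so the image metric responds to the *shape* of the PSF rather than to the
    total flux.
    """
    p = psf_from_wavefront(w, cfg)
    p2 = p * p
    return p2 / p2.sum()


def crop_center(psf: np.ndarray, size: int) -> np.ndarray:
    """Central size x size window of a padded PSF (kernel for image formation)."""
    n = psf.shape[0]
    lo = n // 2 - size // 2
    return psf[lo : lo + size, lo : lo + size]


def reference_peak(phantom: Phantom, cfg: OpticalConfig, grid: PupilGrid) -> float:
    """Peak of the noiseless zero-aberration image; anchors the photon budget."""
    psf0 = crop_center(confocal_psf(Wavefront.zero(grid), cfg), cfg.image_size)
    ref = _circular_convolve(phantom.density, psf0)
    return float(ref.max())


def _circular_convolve(density: np.ndarray, psf: np.ndarray) -> np.ndarray:
    k = scipy.fft.rfft2(scipy.fft.ifftshift(psf))
    out = scipy.fft.irfft2(scipy.fft.rfft2(density) * k, s=density.shape)
    return np.maximum(out, 0.0)


def render_image(
    phantom: Phantom,
    w_total: Wavefront,
    cfg: OpticalConfig,
    noise: NoiseModel | None = None,
    *,
    scale: float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulated confocal image of ``phantom`` under total wavefront ``w_total``.

    The noiseless image is the circular convolution of the phantom with the
    confocal PSF, scaled so the *zero-aberration* reference image peaks at
    ``noise.photon_scale`` photons (pass ``scale`` to reuse a precomputed
    photon_scale / reference_peak factor).  Poisson noise is applied per
    pixel, then Gaussian read noise; the result is clamped at zero and
    returned in floating point.  Pass ``noise=None`` for a noiseless render.
    """
    if phantom.density.shape != (cfg.image_size, cfg.image_size):
        raise ValueError(
            f"phantom shape {phantom.density.shape} != image size "
            f"({cfg.image_size}, {cfg.image_size})"
        )
    psf = crop_center(confocal_psf(w_total, cfg), cfg.image_size)
    img = _circular_convolve(phantom.density, psf)
    if noise is None:
        return img
    if scale is None:
        scale = noise.photon_scale / reference_peak(phantom, cfg, w_total.grid)
    img = img * scale
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    noisy = rng.poisson(img).astype(float)
    if noise.read_sigma > 0:
        noisy += rng.normal(0.0, noise.read_sigma, size=noisy.shape)
    return np.maximum(noisy, 0.0)


def _apron(size: int, width: int = 8) -> np.ndarray:
    """Cosine taper to zero over ``width`` pixels at every edge (wrap-around guard)."""
    ramp = np.ones(size)
    t = 0.5 * (1.0 - np.cos(np.pi * (np.arange(width) + 0.5) / width))
    ramp[:width] = t
    ramp[-width:] = t[::-1]
    return np.outer(ramp, ramp)


def make_phantom(kind: str, size: int = 128, seed: int = 0) -> Phantom:
    """Synthetic fluorophore-density object standing in for a biological specimen.

    kinds: ``beads`` (regular grid of Gaussian spots), ``bars`` (stripe
    pattern), ``tissue`` (filamentary structure from the zero level set of a
    smoothed random field).  All are nonnegative, peak-normalized to 1 and
    tapered at the borders to suppress convolution wrap-around.
    """
    if size < 32:
        raise ValueError(f"size must be >= 32, got {size}")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    if kind == "beads":
        img = np.zeros((size, size))
        spacing = size // 8
        sigma = 1.5
        jitter = rng.uniform(-2.0, 2.0, size=(8, 8, 2))
        for a in range(8):
            for b in range(8):
                cx = spacing // 2 + a * spacing + jitter[a, b, 0]
                cy = spacing // 2 + b * spacing + jitter[a, b, 1]
                img += np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
    elif kind == "bars":
        period = max(8, size // 10)
        img = 0.5 * (1.0 + np.sign(np.sin(2 * np.pi * xx / period)))
        img = ndimage.gaussian_filter(img, 0.8)
    elif kind == "tissue":
        field = ndimage.gaussian_filter(rng.standard_normal((size, size)), size / 24)
        field /= np.abs(field).max()
        # filaments along the zero level set of the smoothed field
        img = np.exp(-((field / 0.15) ** 2))
    else:
        raise ValueError(f"unknown phantom kind: {kind!r}")
    img = img * _apron(size)
    img = np.maximum(img, 0.0)
    return Phantom(img / img.max())
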