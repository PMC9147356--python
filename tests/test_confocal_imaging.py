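import numpy as np
import pytest

from confocal_ao.confocal_imaging import (
    NoiseModel,
    OpticalConfig,
    Phantom,
    confocal_psf,
    crop_center,
    make_phantom,
    psf_from_wavefront,
    render_image,
)
from confocal_ao.metrics import variance_metric
from confocal_ao.wavefront import Wavefront, compose_wavefront, random_aberration


@pytest.fixture(scope="module")
def cfg():
    return OpticalConfig()


def _half_width(profile):
    """Interpolated half-max crossing distance of a radial profile from its peak."""
    p = profile / profile[0]
    idx = np.argmax(p < 0.5)
    return idx - 1 + (p[idx - 1] - 0.5) / (p[idx - 1] - p[idx])


def test_unaberrated_psf_peak_and_airy_zero(grid128, cfg):
    psf = psf_from_wavefront(Wavefront.zero(grid128), cfg)
    n = psf.shape[0]
    assert np.unravel_index(psf.argmax(), psf.shape) == (n // 2, n // 2)

    prof = psf[n // 2, n // 2 :]
    minima = [k for k in range(1, 40) if prof[k] < prof[k - 1] and prof[k] <= prof[k + 1]]
    assert abs(minima[0] - cfg.airy_radius_px(grid128)) <= 1.0


def test_psf_unit_sum(grid128, cfg):
    for w in (Wavefront.zero(grid128), random_aberration(1.0, 10, 0, grid128)):
        assert psf_from_wavefront(w, cfg).sum() == pytest.approx(1.0, abs=1e-9)
        assert confocal_psf(w, cfg).sum() == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize("noll", [4, 5, 6, 7, 8, 11])
def test_strehl_near_marechal_for_unit_rms_modes(grid128, cfg, noll):
    """1 rad RMS of a single mode gives Strehl within 20% of exp(-1)."""
    p0 = psf_from_wavefront(Wavefront.zero(grid128), cfg).max()
    p = psf_from_wavefront(compose_wavefront({noll: 1.0}, grid128), cfg).max()
    strehl = p / p0
    assert 0.8 * np.exp(-1) <= strehl <= 1.2 * np.exp(-1)


def test_confocal_psf_is_sharper(grid128, cfg):
    pw = psf_from_wavefront(Wavefront.zero(grid128), cfg)
    pc = confocal_psf(Wavefront.zero(grid128), cfg)
    n = pw.shape[0]
    assert _half_width(pc[n // 2, n // 2 :]) < _half_width(pw[n // 2, n // 2 :])


def test_confocal_double_pass_penalizes_aberration_twice(grid128, cfg):
    """Peak of the raw product drops as the square of the widefield Strehl."""
    p0 = psf_from_wavefront(Wavefront.zero(grid128), cfg)
    for seed in range(10):
        p = psf_from_wavefront(random_aberration(0.8, 15, seed, grid128), cfg)
        strehl_wide = p.max() / p0.max()
        strehl_conf = (p**2).max() / (p0**2).max()
        assert strehl_conf < strehl_wide < 1.0


def test_render_delta_phantom_reproduces_psf(cfg, grid128):
    delta = np.zeros((128, 128))
    delta[40, 90] = 1.0
    img = render_image(Phantom(delta), Wavefront.zero(grid128), cfg, None)
    kernel = crop_center(confocal_psf(Wavefront.zero(grid128), cfg), 128)
    rolled = np.roll(np.roll(kernel, 40 - 64, axis=0), 90 - 64, axis=1)
    assert np.allclose(img, rolled, atol=1e-12)


def test_render_constant_phantom_is_constant(cfg, grid128):
    img = render_image(Phantom(np.full((128, 128), 0.7)), Wavefront.zero(grid128), cfg, None)
    assert np.ptp(img) < 1e-9 * img.mean()


def test_render_linear_in_phantom_before_noise(cfg, grid128):
    ph = make_phantom("tissue", 128, 3)
    w = random_aberration(0.8, 10, 1, grid128)
    a = render_image(Phantom(ph.density), w, cfg, None)
    b = render_image(Phantom(2.0 * ph.density), w, cfg, None)
    assert np.allclose(b, 2.0 * a, rtol=1e-9, atol=1e-12)


def test_render_seeded_determinism(cfg, grid128):
    ph = make_phantom("beads", 128, 0)
    w = random_aberration(1.0, 12, 2, grid128)
    noise = NoiseModel(seed=7)
    img1 = render_image(ph, w, cfg, noise)
    img2 = render_image(ph, w, cfg, noise)
    assert np.array_equal(img1, img2)
    img3 = render_image(ph, w, cfg, NoiseModel(seed=8))
    assert not np.array_equal(img1, img3)


def test_render_size_mismatch(cfg, grid128):
    with pytest.raises(ValueError):
        render_image(make_phantom("beads", 64, 0), Wavefront.zero(grid128), cfg, None)


def test_aberration_lowers_variance_metric(cfg, grid128):
    """The premise of image-based correction: blur lowers the variance metric."""
    ph = make_phantom("beads", 128, 0)
    j0 = variance_metric(render_image(ph, Wavefront.zero(grid128), cfg, None))
    hits = sum(
        variance_metric(render_image(ph, random_aberration(1.2, 15, s, grid128), cfg, None)) < j0
        for s in range(20)
    )
    assert hits >= 19  # >= 95% of 20 aberration draws


def test_metric_monotone_in_ensemble_mean(cfg, grid128):
    ph = make_phantom("beads", 128, 0)
    means = []
    for rms in (0.0, 0.5, 1.0, 1.5):
        vals = []
        for seed in range(20):
            w = (
                random_aberration(rms, 15, seed, grid128)
                if rms > 0
                else Wavefront.zero(grid128)
            )
            vals.append(variance_metric(render_image(ph, w, cfg, None)))
        means.append(np.mean(vals))
    assert all(a > b for a, b in zip(means, means[1:]))


def test_phantom_kinds(cfg):
    beads = make_phantom("beads", 128, 1)
    assert beads.density.min() >= 0 and beads.density.max() == pytest.approx(1.0)
    assert (beads.density > 0.1).mean() > 0.05

    assert np.array_equal(beads.density, make_phantom("beads", 128, 1).density)

    with pytest.raises(ValueError):
        make_phantom("squares", 128, 0)
    with pytest.raises(ValueError):
        make_phantom("beads", 16, 0)


def test_tissue_coarser_than_beads():
    def autocorr_halfwidth(im):
        im = im - im.mean()
        f = np.fft.rfft2(im)
        ac = np.fft.irfft2(f * np.conj(f), s=im.shape)
        ac = np.fft.fftshift(ac) / ac.max()
        c = im.shape[0] // 2
        prof = ac[c, c:]
        return np.argmax(prof < 0.5)

    assert autocorr_halfwidth(make_phantom("tissue", 128, 0).density) > autocorr_halfwidth(
        make_phantom("beads", 128, 0).density
    )
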