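# Methods

This note documents the simulated optical bench, the optimizer, the choice of
every default parameter, and the known limitations of the model.

## 1. Wavefront model

Phase aberrations are expanded in Zernike polynomials on a sampled circular
pupil (`PupilGrid`, 128×128 samples, aperture radius 0.45 of the grid width).
Modes use **Noll single-indexing** and **Noll normalization**: every mode of
index ≥ 2 has unit RMS over the continuous pupil, so a coefficient vector's
Euclidean norm is the wavefront RMS in radians. `noll_to_nm` implements the
standard recurrence (odd index → sine/negative-m term). On the discrete grid
the sampled modes are orthogonal only to ~1e-2; tests use tolerances at that
level, not machine precision.

Random aberrations (`random_aberration`) draw Noll modes 4..max_index
(piston, tip and tilt are excluded — they do not blur a confocal image, only
shift it) with standard deviation ∝ 1/index (low-order-dominated, as in real
systems), then rescale exactly to the requested RMS. Default: 1.2 rad RMS
over modes 4..15.

## 2. Deformable mirror

`default_layout_69` places a 9×9 actuator grid spanning **0.95** of the
pupil radius and removes three actuators per corner (removal rule
`min(i, 8−i) + min(j, 8−j) < 2`), leaving 69 actuators. Each actuator has a
Gaussian influence function with **15 % nearest-neighbour coupling**
(`w² = pitch² / ln(1/0.15)`). Mirror phase is the linear superposition
`stroke_gain · Σ uⱼ fⱼ(x, y)` with commands clipped to [−1, 1].

- **Span = 0.95** was calibrated once against a least-squares fitting
  oracle: projecting 0.8-rad aberrations (Noll 4–10) onto the influence
  basis must remove most of the variance. At span 0.8 the pupil edge was
  uncovered (≈ 50 % residual); 0.95 achieves ≥ 88 % residual reduction while
  keeping all actuators within 1.1× the pupil radius.
- **stroke_gain = 5π rad per unit command** converts the dimensionless
  command to phase (≈ 2.5 waves; the reflective double pass is absorbed into
  the constant). It was calibrated once so that the standard ±0.005 command
  perturbation drives metric changes on the scale the optimizer's defaults
  assume: at 2π the loop climbed an order of magnitude too slowly, at 4π the
  adaptive mode was occasionally unstable, at 5π both modes reproduce the
  intended dynamics (metric ≈ 4 → 8–9 within 100 iterations).

## 3. Confocal image formation

`psf_from_wavefront` computes the widefield intensity PSF as
`|FFT(mask · exp(iφ))|²` on a 4×-padded grid (128-pixel pupil → 512-pixel
FFT plane), normalized to unit sum over the *full* padded plane. The
confocal kernel is the **squared** widefield PSF (pinhole-limited detection
through the same aberrated path), renormalized to unit sum — the
renormalization stands in for detector-gain adjustment; see Limitations.
The kernel is then cropped to the 128×128 image size **without**
renormalizing, so light scattered outside the field of view is genuinely
lost. Images are formed by circular FFT convolution with a synthetic
phantom; phantoms carry an 8-pixel cosine-taper apron so wrap-around is
negligible.

At the defaults the unaberrated PSF's first dark ring sits at
`1.22 · N_fft / D_pupil ≈ 5.4` pixels, and single-mode Strehl ratios at 1 rad
RMS fall in the Maréchal band around `e⁻¹` — both pinned by tests.

**Noise.** Detected images are `Poisson(photon_scale · conv) + N(0, read_sigma²)`,
clamped at zero. Defaults `photon_scale = 500` (peak photons at the
zero-aberration reference) and `read_sigma = 2` give a realistic confocal
SNR where the metric's iteration-to-iteration noise is visible but does not
dominate the bilateral difference. Every metric evaluation uses an
independent, reproducible noise substream
`default_rng([noise_seed, eval_index])`, so the optimizer never sees the
same noise twice yet runs are bit-reproducible.

**Phantoms** (`make_phantom`): `beads` (jittered 8×8 grid of σ = 1.5 px
Gaussian spots — the default; rich in high frequencies, ideal for a variance
metric), `bars` (smoothed stripes), `tissue` (smoothed-random-field
filaments with broader autocorrelation).

## 4. Image-quality metric

`variance_metric(I) = mean((I − mean(I))²)` (population divisor). Sharper
images concentrate photons and raise the variance, so maximizing it drives
aberration correction. `sharpness` (mean square) and `brightness` (mean) are
available through the same registry.

**Metric scale.** The gain law's clamp level `J₀ = 10` presumes a metric of
order 10 at convergence. The bench therefore calibrates one scale factor per
configuration: the noiseless zero-aberration reference image scores
`metric_reference = 9.5` — just below J₀, so the exponential fade-out term
is reachable but never saturated. This is a model-closure constant fixed
from the intended operating point, recorded in every run manifest.

## 5. SPGD optimizer

Per iteration: draw Bernoulli `δu ∈ {−σ, +σ}ⁿ` (σ = 0.005), evaluate
`J(u ± δu)`, form `δJ = ½(J⁺ − J⁻)`, update `u ← clip(u + γ δJ δu)`.
`δJ·δu/σ²` is an unbiased one-sample estimate of the metric gradient (its
average over repeated draws correlates ≥ 0.95 with finite differences — a
pinned test). Fixed mode uses γ = 5 and exactly 2 metric evaluations per
iteration; adaptive mode adds a baseline evaluation `J(u)` (3 per
iteration). Budget: 100 iterations. A non-finite metric aborts with the
iteration index.

**Plateau rule:** convergence is declared at the first iteration of a run of
10 consecutive iterations in which the 10-iteration moving average of the
metric changes by < 1 % relative. It is reported post hoc; the loop runs the
full budget unless `stop_on_plateau` is set.

## 6. Adaptive gain law

```
γ(k+1) = γ(k) + α (γ₀ − γ(k)) + β(k) H(k)
β      = ξ |sign(ΔJ⁺) − sign(ΔJ⁻)|              (sign(0) = 0 ⇒ β ∈ {0, ξ, 2ξ})
H      = |δJ| Σ_{l=1..L} |J(k) − J(k−l)| exp(−1/(J₀−J)),   H = 0 for J ≥ J₀
```

Defaults: γ₀ = 4, α = 0.9, ξ = 15, L = 5, J₀ = 10, floor γ_min = 0.1.
Interpretation: the first correction term contracts γ geometrically toward
γ₀ with ratio (1 − α) = 0.1; β fires when the two one-sided metric changes
disagree in sign (the perturbation straddled a ridge — the step was
informative), and H gates that boost by how much the metric is still moving
over the last L iterations, fading exponentially as J approaches J₀.

**Warm-up.** The scheduler stores baselines from records 1..4 and computes
its first update from the record of iteration 5, so the gain *used* at
iterations 1–5 equals `gamma_init` and iteration 6 is the first that can
differ. The history sum runs over however many entries exist (≤ L).

In the closed loop the gain typically spikes to 8–12 within the first ~15
iterations while the metric climbs, then settles at γ₀: across 20 seeds the
mean gain over the final 10 of 100 iterations is ≈ 4.10 (the small offset
above 4 comes from residual sign-disagreement events near the plateau).
Adaptive mode converges no slower than fixed (median plateau iteration 28 vs
31.5 over 20 paired seeds) at equal final quality.

## 7. Experiments, reproducibility, artifacts

`ExperimentConfig` is a frozen dataclass serializable to a flat
`key = value` text format; `run_experiment` writes `run.csv` (per-iteration
trace), `manifest.txt` (every consumed parameter — re-running from a
manifest reproduces the run byte for byte), before/after PNG and float
TIFF images, and the residual wavefront as TIFF. `run_comparison` runs
fixed and adaptive modes on identical per-seed benches (same phantom,
aberration and noise streams) and aggregates medians/IQRs. All randomness
derives from the single run seed via `SeedSequence` splitting into phantom,
aberration and noise sub-seeds.

## 8. Limitations

- The confocal kernel's unit-sum renormalization hides the double-pass flux
  penalty (treated as automatic detector gain). The physical peak-intensity
  penalty is still asserted on the un-renormalized squared PSFs.
- The pinhole is implicitly ideal (infinitesimal): detection PSF equals the
  illumination PSF. Finite pinhole size, vignetting, and scan-position
  dependence of the aberration are not modelled (isoplanatic patch assumed).
- The DM is linear, hysteresis-free and instantaneous; saturation is the
  only nonlinearity. Real mirrors add creep, hysteresis and temporal
  dynamics.
- `stroke_gain`, actuator span and `metric_reference` are model-closure
  calibrations (see §2, §4), fixed once from physical/operating-point
  considerations and never adjusted afterwards.
- The variance metric is phantom-dependent; sparse, high-frequency scenes
  (beads) give the cleanest gradient signal. The `tissue` phantom shows the
  same qualitative behaviour with a weaker signal.
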