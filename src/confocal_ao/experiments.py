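"""Closed-loop experiments on the simulated confocal bench.

A :class:`SimulatedBench` bundles phantom, static unknown aberration,
deformable-mirror model and detector noise into a single objective
u -> J(image), where J is the (scaled) grayscale-variance metric of the
rendered image.  :func:`run_experiment` runs one optimizer on it;
:func:`run_comparison` pairs the fixed- and adaptive-gain optimizers on
identical aberration/noise realizations across seeds.

Metric scale: the raw variance of a photon-count image depends on the photon
budget, so the objective is calibrated once per bench such that the
noiseless, zero-aberration reference image scores ``metric_reference``
(default 9.5).  This puts the metric on the same footing as the gain law's
desired level J0 = 10, mirroring how a real instrument's display scaling
fixes the magnitude of its image metric.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .adaptive_gain import AdaptiveGainConfig, AdaptiveGainScheduler
from .confocal_imaging import (
    NoiseModel,
    OpticalConfig,
    Phantom,
    confocal_psf,
    crop_center,
    make_phantom,
    render_image,
    _circular_convolve,
)
from .deformable_mirror import (
    ControlVector,
    InfluenceModel,
    default_layout_69,
    influence_matrix,
)
from .metrics import get_metric
from .spgd_core import RunResult, SPGDConfig, run_spgd
from .wavefront import PupilGrid, Wavefront, random_aberration, rms_error

__all__ = [
    "ExperimentConfig",
    "SimulatedBench",
    "ExperimentResult",
    "ComparisonSummary",
    "run_experiment",
    "run_comparison",
    "line_profile",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one closed-loop run."""

    optics: OpticalConfig = OpticalConfig()
    pupil_samples: int = 128
    aperture_frac: float = 0.45
    phantom_kind: str = "beads"
    phantom_seed: int = 0
    aberration_rms: float = 1.2
    aberration_max_index: int = 15
    photon_scale: float = 500.0
    read_sigma: float = 2.0
    dm_coupling: float = 0.15
    dm_stroke_gain: float = 5.0 * np.pi
    u_max: float = 1.0
    spgd: SPGDConfig = SPGDConfig()
    adaptive: AdaptiveGainConfig = AdaptiveGainConfig()
    metric_name: str = "variance"
    metric_reference: float = 9.5
    mode: str = "fixed"
    seed: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "adaptive"):
            raise ValueError("mode must be 'fixed' or 'adaptive'")

    # ---- flat key=value serialization (config files and run manifests) ----

    def to_flat(self) -> dict[str, object]:
        d: dict[str, object] = {
            "optics.wavelength_nm": self.optics.wavelength_nm,
            "optics.numerical_aperture": self.optics.numerical_aperture,
            "optics.image_size": self.optics.image_size,
            "optics.pad_factor": self.optics.pad_factor,
            "pupil.n_samples": self.pupil_samples,
            "pupil.aperture_frac": self.aperture_frac,
            "phantom.kind": self.phantom_kind,
            "phantom.seed": self.phantom_seed,
            "aberration.rms": self.aberration_rms,
            "aberration.max_index": self.aberration_max_index,
            "noise.photon_scale": self.photon_scale,
            "noise.read_sigma": self.read_sigma,
            "dm.coupling": self.dm_coupling,
            "dm.stroke_gain": self.dm_stroke_gain,
            "dm.u_max": self.u_max,
            "spgd.perturbation_amplitude": self.spgd.perturbation_amplitude,
            "spgd.gain": self.spgd.gain,
            "spgd.max_iterations": self.spgd.max_iterations,
            "spgd.stop_on_plateau": self.spgd.stop_on_plateau,
            "adaptive.gamma0": self.adaptive.gamma0,
            "adaptive.alpha": self.adaptive.alpha,
            "adaptive.xi": self.adaptive.xi,
            "adaptive.history_window": self.adaptive.history_window,
            "adaptive.J_target": self.adaptive.J_target,
            "adaptive.gamma_init": (
                "none" if self.adaptive.gamma_init is None else self.adaptive.gamma_init
            ),
            "adaptive.gamma_min": self.adaptive.gamma_min,
            "metric.name": self.metric_name,
            "metric.reference_level": self.metric_reference,
            "mode": self.mode,
            "seed": self.seed,
        }
        return d

    def to_text(self) -> str:
        return "\n".join(f"{k} = {v}" for k, v in self.to_flat().items()) + "\n"

    @classmethod
    def from_flat(cls, d: dict[str, str]) -> "ExperimentConfig":
        def get(key, cast, default):
            if key not in d:
                return default
            v = d[key]
            if cast is bool and isinstance(v, str):
                return v.strip().lower() in ("true", "1", "yes")
            return cast(v)

        base = cls()
        gamma_init_raw = d.get("adaptive.gamma_init", "none")
        gamma_init = None if str(gamma_init_raw).strip().lower() == "none" else float(gamma_init_raw)
        return cls(
            optics=OpticalConfig(
                wavelength_nm=get("optics.wavelength_nm", float, base.optics.wavelength_nm),
                numerical_aperture=get(
                    "optics.numerical_aperture", float, base.optics.numerical_aperture
                ),
                image_size=get("optics.image_size", int, base.optics.image_size),
                pad_factor=get("optics.pad_factor", int, base.optics.pad_factor),
            ),
            pupil_samples=get("pupil.n_samples", int, base.pupil_samples),
            aperture_frac=get("pupil.aperture_frac", float, base.aperture_frac),
            phantom_kind=get("phantom.kind", str, base.phantom_kind),
            phantom_seed=get("phantom.seed", int, base.phantom_seed),
            aberration_rms=get("aberration.rms", float, base.aberration_rms),
            aberration_max_index=get("aberration.max_index", int, base.aberration_max_index),
            photon_scale=get("noise.photon_scale", float, base.photon_scale),
            read_sigma=get("noise.read_sigma", float, base.read_sigma),
            dm_coupling=get("dm.coupling", float, base.dm_coupling),
            dm_stroke_gain=get("dm.stroke_gain", float, base.dm_stroke_gain),
            u_max=get("dm.u_max", float, base.u_max),
            spgd=SPGDConfig(
                perturbation_amplitude=get(
                    "spgd.perturbation_amplitude", float, base.spgd.perturbation_amplitude
                ),
                gain=get("spgd.gain", float, base.spgd.gain),
                max_iterations=get("spgd.max_iterations", int, base.spgd.max_iterations),
                stop_on_plateau=get("spgd.stop_on_plateau", bool, base.spgd.stop_on_plateau),
            ),
            adaptive=AdaptiveGainConfig(
                gamma0=get("adaptive.gamma0", float, base.adaptive.gamma0),
                alpha=get("adaptive.alpha", float, base.adaptive.alpha),
                xi=get("adaptive.xi", float, base.adaptive.xi),
                history_window=get("adaptive.history_window", int, base.adaptive.history_window),
                J_target=get("adaptive.J_target", float, base.adaptive.J_target),
                gamma_init=gamma_init,
                gamma_min=get("adaptive.gamma_min", float, base.adaptive.gamma_min),
            ),
            metric_name=get("metric.name", str, base.metric_name),
            metric_reference=get("metric.reference_level", float, base.metric_reference),
            mode=get("mode", str, base.mode),
            seed=get("seed", int, base.seed),
        )

    @classmethod
    def from_text(cls, text: str) -> "ExperimentConfig":
        d: dict[str, str] = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            k, v = line.split("=", 1)
            d[k.strip()] = v.strip()
        return cls.from_flat(d)

    @classmethod
    def load(cls, path) -> "ExperimentConfig":
        return cls.from_text(Path(path).read_text())


def _derive_seeds(run_seed: int) -> tuple[int, int, int]:
    """(aberration, noise, spgd) sub-seeds, all below 2**31."""
    state = np.random.SeedSequence(run_seed).generate_state(3)
    return tuple(int(s % (2**31)) for s in state)


class SimulatedBench:
    """Phantom + aberration + mirror + detector, exposed as an objective u -> J."""

    def __init__(self, cfg: ExperimentConfig, run_seed: Optional[int] = None):
        self.cfg = cfg
        run_seed = cfg.seed if run_seed is None else run_seed
        self.run_seed = run_seed
        self.aberration_seed, self.noise_seed, self.spgd_seed = _derive_seeds(run_seed)

        self.grid = PupilGrid(cfg.pupil_samples, cfg.aperture_frac * cfg.pupil_samples)
        self.layout = default_layout_69()
        self.influence = InfluenceModel(coupling=cfg.dm_coupling, stroke_gain=cfg.dm_stroke_gain)
        self._G = influence_matrix(self.layout, self.influence, self.grid)
        self.phantom = make_phantom(cfg.phantom_kind, cfg.optics.image_size, cfg.phantom_seed)
        if cfg.aberration_rms > 0:
            self.aberration = random_aberration(
                cfg.aberration_rms, cfg.aberration_max_index, self.aberration_seed, self.grid
            )
        else:
            self.aberration = Wavefront.zero(self.grid)
        self.noise = NoiseModel(cfg.photon_scale, cfg.read_sigma, self.noise_seed)
        self._metric = get_metric(cfg.metric_name)

        # photon calibration: zero-aberration noiseless image peaks at photon_scale
        ref = _circular_convolve(
            self.phantom.density,
            crop_center(confocal_psf(Wavefront.zero(self.grid), cfg.optics), cfg.optics.image_size),
        )
        self.photon_factor = cfg.photon_scale / float(ref.max())
        # metric calibration: the same reference image scores metric_reference
        self.metric_scale = cfg.metric_reference / self._metric(ref * self.photon_factor)
        self._eval_counter = itertools.count()

    def total_wavefront(self, u: ControlVector) -> Wavefront:
        return Wavefront(
            self.aberration.phase + np.tensordot(u.u, self._G, axes=(0, 0)), self.grid
        )

    def render(self, u: ControlVector, noisy: bool = True, eval_index: Optional[int] = None):
        """Image seen at command ``u``; noise drawn from a per-evaluation substream."""
        w = self.total_wavefront(u)
        if not noisy:
            return render_image(self.phantom, w, self.cfg.optics, None) * self.photon_factor
        if eval_index is None:
            eval_index = next(self._eval_counter)
        rng = np.random.default_rng([self.noise_seed, eval_index])
        return render_image(
            self.phantom, w, self.cfg.optics, self.noise, scale=self.photon_factor, rng=rng
        )

    def metric_of(self, image: np.ndarray) -> float:
        return self.metric_scale * self._metric(image)

    def objective(self, u: ControlVector) -> float:
        return self.metric_of(self.render(u))

    def residual_rms(self, u: ControlVector) -> float:
        return rms_error(self.total_wavefront(u))


@dataclass
class ExperimentResult:
    cfg: ExperimentConfig
    run_seed: int
    mode: str
    run: RunResult
    initial_rms: float
    final_rms: float
    initial_metric: float
    final_metric: float
    initial_image: np.ndarray
    final_image: np.ndarray
    gain_trace: np.ndarray


def _write_png(path, image: np.ndarray, vmax: Optional[float] = None) -> None:
    """8-bit PNG export with linear scaling (0 -> 0, vmax -> 255)."""
    import imageio.v3 as iio

    m = float(image.max()) if vmax is None else float(vmax)
    scaled = np.clip(image / m if m > 0 else image, 0, 1)
    iio.imwrite(path, (255 * scaled).astype(np.uint8))


def run_experiment(
    cfg: ExperimentConfig,
    out_dir=None,
    run_seed: Optional[int] = None,
    bench: Optional[SimulatedBench] = None,
) -> ExperimentResult:
    """Run one optimizer (cfg.mode) on the simulated bench; optionally write artifacts.

    Artifacts: ``run.csv`` (per-iteration trace), ``manifest.txt`` (every
    parameter, round-trippable), initial/final images (PNG + float TIFF) and
    the residual-wavefront TIFF.
    """
    out = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")  # fail before any computation if unwritable
        probe.unlink()

    if bench is None:
        bench = SimulatedBench(cfg, run_seed=run_seed)
    scheduler = AdaptiveGainScheduler(cfg.adaptive) if cfg.mode == "adaptive" else None
    spgd_cfg = replace(cfg.spgd, seed=bench.spgd_seed, u_max=cfg.u_max)

    u0 = ControlVector.zeros(bench.layout.count, u_max=cfg.u_max)
    initial_image = bench.render(u0, noisy=True, eval_index=2**30)  # out-of-band substream
    initial_metric = bench.metric_of(initial_image)
    initial_rms = bench.residual_rms(u0)

    run = run_spgd(
        bench.objective, bench.layout.count, spgd_cfg, gain_schedule=scheduler, u0=u0
    )

    final_image = bench.render(run.final_u, noisy=True, eval_index=2**30 + 1)
    result = ExperimentResult(
        cfg=cfg,
        run_seed=bench.run_seed,
        mode=cfg.mode,
        run=run,
        initial_rms=initial_rms,
        final_rms=bench.residual_rms(run.final_u),
        initial_metric=initial_metric,
        final_metric=bench.metric_of(final_image),
        initial_image=initial_image,
        final_image=final_image,
        gain_trace=run.gain_trace(),
    )

    if out is not None:
        run.to_csv(out / "run.csv")
        (out / "manifest.txt").write_text(
            cfg.to_text() + f"run.seed = {bench.run_seed}\nrun.mode = {cfg.mode}\n"
        )
        import tifffile

        vmax = max(initial_image.max(), final_image.max())
        _write_png(out / "initial.png", initial_image, vmax)
        _write_png(out / "final.png", final_image, vmax)
        tifffile.imwrite(out / "initial.tiff", initial_image.astype(np.float32))
        tifffile.imwrite(out / "final.tiff", final_image.astype(np.float32))
        tifffile.imwrite(
            out / "residual_wavefront.tiff",
            bench.total_wavefront(run.final_u).phase.astype(np.float32),
        )
    return result


@dataclass
class ComparisonSummary:
    """Paired fixed-vs-adaptive results over a list of seeds."""

    table: pd.DataFrame  # one row per (seed, mode)
    results: dict[tuple[int, str], ExperimentResult] = field(default_factory=dict)

    def aggregates(self) -> pd.DataFrame:
        g = self.table.groupby("mode")
        return pd.DataFrame(
            {
                "median_final_metric": g["final_metric"].median(),
                "iqr_final_metric": g["final_metric"].quantile(0.75)
                - g["final_metric"].quantile(0.25),
                "median_convergence_iteration": g["convergence_iteration"].median(),
                "median_final_rms": g["final_rms"].median(),
            }
        )

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def run_comparison(
    cfg: ExperimentConfig,
    seeds: list[int],
    modes: tuple[str, ...] = ("fixed", "adaptive"),
    keep_results: bool = True,
) -> ComparisonSummary:
    """Run both optimizers on identical (phantom, aberration, noise) per seed."""
    if not seeds:
        raise ValueError("seed list must be nonempty")
    rows = []
    results: dict[tuple[int, str], ExperimentResult] = {}
    for seed in seeds:
        for mode in modes:
            mode_cfg = replace(cfg, mode=mode, seed=seed)
            res = run_experiment(mode_cfg, run_seed=seed)
            rows.append(
                {
                    "seed": seed,
                    "mode": mode,
                    "initial_metric": res.initial_metric,
                    "final_metric": res.final_metric,
                    "convergence_iteration": res.run.convergence_iteration,
                    "initial_rms": res.initial_rms,
                    "final_rms": res.final_rms,
                    "final_gain": res.gain_trace[-1],
                }
            )
            if keep_results:
                results[(seed, mode)] = res
    return ComparisonSummary(table=pd.DataFrame(rows), results=results)


def line_profile(image: np.ndarray, row_index: int) -> np.ndarray:
    """Pixel values along one image row (the simulated twin of a line-scan plot)."""
    image = np.asarray(image)
    if not 0 <= row_index < image.shape[0]:
        raise ValueError(f"row {row_index} out of bounds for image with {image.shape[0]} rows")
    return image[row_index].copy()
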