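import numpy as np
import pytest

from confocal_ao.experiments import ExperimentConfig, run_comparison
from confocal_ao.wavefront import PupilGrid


@pytest.fixture(scope="session")
def grid128():
    return PupilGrid(128)


@pytest.fixture(scope="session")
def grid256():
    return PupilGrid(256)


@pytest.fixture(scope="session")
def paired_comparison():
    """Fixed vs adaptive SPGD over 20 paired seeds at the default bench settings.

    This is the package's main simulated experiment (beads phantom, 1.2 rad
    RMS aberration, 69-actuator mirror, 100 iterations); several convergence
    and efficacy checks share it.
    """
    return run_comparison(ExperimentConfig(), list(range(20)))


def small_config(**overrides) -> ExperimentConfig:
    """A 64-pixel bench for fast functional tests."""
    from dataclasses import replace
    from confocal_ao.confocal_imaging import OpticalConfig
    from confocal_ao.spgd_core import SPGDConfig

    cfg = ExperimentConfig(
        optics=OpticalConfig(image_size=64),
        pupil_samples=64,
        spgd=SPGDConfig(max_iterations=12),
    )
    return replace(cfg, **overrides) if overrides else cfg
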