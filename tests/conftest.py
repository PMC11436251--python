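import numpy as np
import pytest

from glucosens.optical_model import skin_three_layer
from glucosens.photon_transport import DetectorGrid, SimulationConfig, run_mc


@pytest.fixture(scope="session")
def detectors():
    return DetectorGrid()


@pytest.fixture(scope="session")
def skin_1314():
    return skin_three_layer(1314.0)


@pytest.fixture(scope="session")
def skin_record(skin_1314, detectors):
    """One converged reflectance run on the anchor-wavelength skin model."""
    return run_mc(skin_1314, detectors, SimulationConfig(n_photons=1_000_000, seed=42))


@pytest.fixture(scope="session")
def mus_sweep_fits(skin_1314, detectors):
    """Per-ring slope fits of A vs dermis mu_s (moderate photon budget)."""
    from glucosens.sensitivity_analysis import partial_wrt_mus

    cfg = SimulationConfig(n_photons=400_000, seed=11)
    return partial_wrt_mus(skin_1314, detectors, [5, 7, 9, 11, 13], cfg)


@pytest.fixture(scope="session")
def mua_sweep_fits(skin_1314, detectors):
    """Per-ring slope fits of A vs dermis mu_a."""
    from glucosens.sensitivity_analysis import partial_wrt_mua

    base = skin_1314.layer("dermis").props.mu_a
    cfg = SimulationConfig(n_photons=1_000_000, seed=12)
    sweep = [base + off for off in (0.0, 0.25, 0.5, 0.75, 1.0)]
    return partial_wrt_mua(skin_1314, detectors, sweep, cfg)
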