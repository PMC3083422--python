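import numpy as np
import pytest

from neutroskin import microdosim as md
from neutroskin.synthetic import NoiseModel, PlantedEffects, StudyDesign


@pytest.fixture(scope="session")
def small_design() -> StudyDesign:
    return StudyDesign(n_genes=300, replicates_per_condition=2, mice_per_group=4)


@pytest.fixture(scope="session")
def small_effects(small_design) -> PlantedEffects:
    return PlantedEffects.default(small_design)


@pytest.fixture()
def quiet_noise() -> NoiseModel:
    """No noise, no bias, no flags: measurements equal planted truth."""
    return NoiseModel(spot_sd=0.0, dye_bias_coeffs=(0.0,), flag_rate=0.0,
                      low_signal_rate=0.0, ct_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def lineal_spectrum() -> md.SingleEventSpectrum:
    return md.example_lineal_spectrum()


@pytest.fixture(scope="session")
def specific_spectrum(lineal_spectrum) -> md.SingleEventSpectrum:
    site = md.SphericalSite(diameter=2.0)
    return md.single_event_z_spectrum(lineal_spectrum, site)
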