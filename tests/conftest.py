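import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from uremiq.library import default_library
from uremiq.simulate import AcquisitionParams, PatientSample, simulate_spectrum

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def acq():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def quiet_acq():
    """Noise- and baseline-free acquisition for exact round-trip checks."""
    return AcquisitionParams(noise_sd=0.0, baseline_amplitude=0.0)


@pytest.fixture(scope="session")
def panel_truth(library):
    """Plasma concentrations at the configured uremic cohort means."""
    return {m.name: m.cohort_mean for m in library.simulated()}


@pytest.fixture(scope="session")
def single_metabolite_spectrum(library, quiet_acq):
    """Factory: noiseless spectrum of one metabolite (+ TSP) at a given uM."""

    def make(name: str, conc: float, preparation: str = "ultrafiltration", seed: int = 0):
        sample = PatientSample("S1", {name: conc})
        return simulate_spectrum(sample, preparation, library, quiet_acq, seed=seed)

    return make


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
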