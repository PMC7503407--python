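import numpy as np
import pytest

from aptnet import (
    SimulationConfig,
    default_block_library,
    make_variant,
    simulate_spectrum,
)


@pytest.fixture(scope="session")
def library():
    return default_block_library()


@pytest.fixture(scope="session")
def apt788():
    return make_variant(["Val", "Lys", "Val", "Trp", "MeAla", "Phe"])


@pytest.fixture(scope="session")
def apt802():
    return make_variant(["Val", "Lys", "Ile/Leu", "Trp", "MeAla", "Phe"])


@pytest.fixture(scope="session")
def apt816():
    return make_variant(["Ile/Leu", "Lys", "Ile/Leu", "Trp", "MeAla", "Phe"])


@pytest.fixture
def rng():
    return np.random.default_rng(20200820)


@pytest.fixture
def clean_spectrum(apt802):
    """Noise-free, dropout-free simulated spectrum of the 802 compound."""
    cfg = SimulationConfig(seed=1, ppm_sigma=0.0, fragment_dropout=0.0, n_noise_peaks=0)
    return simulate_spectrum(apt802, cfg, identifier="clean802")


def random_spectrum(rng, n_peaks=None, mz_range=(100.0, 1000.0), identifier="rand"):
    """Shared helper: a random centroided spectrum."""
    from aptnet import Spectrum

    if n_peaks is None:
        n_peaks = int(rng.integers(5, 40))
    mz = rng.uniform(*mz_range, size=n_peaks)
    intensity = rng.lognormal(7.0, 1.0, size=n_peaks)
    precursor = float(rng.uniform(300.0, 1000.0))
    return Spectrum.from_arrays(identifier, precursor, mz, intensity)
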