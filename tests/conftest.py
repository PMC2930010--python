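import numpy as np
import pytest

from qpcrfit.preprocess import AmplificationCurve
from qpcrfit.simulate import GeneratorConfig, generate_dilution_series


@pytest.fixture(scope="session")
def noiseless_config() -> GeneratorConfig:
    """Default study conditions without detector noise."""
    return GeneratorConfig(noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_series(noiseless_config):
    return generate_dilution_series(noiseless_config)


@pytest.fixture(scope="session")
def noisy_series():
    """Default study conditions: 1%-of-plateau noise, duplicate wells."""
    return generate_dilution_series(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def doubling_config() -> GeneratorConfig:
    """Near-ideal doubling curves (k >> signal) for Cq behaviour checks."""
    return GeneratorConfig(
        k=1e6,
        noise_sd=0.0,
        replicates=1,
        n_cycles=45,
        d0_levels=(1e-9, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4),
    )


def make_curve(fluorescence, well_id="w", known_copies=None) -> AmplificationCurve:
    f = np.asarray(fluorescence, dtype=float)
    return AmplificationCurve(
        well_id=well_id,
        cycles=np.arange(1, len(f) + 1),
        fluorescence=f,
        known_copies=known_copies,
    )
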