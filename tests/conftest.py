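import warnings

import pytest

from qlloq.calibration import fit_3pl
from qlloq.synthetic import SimScenario, generate_run

# Dilution-ratio warnings from deliberately ragged fixtures are noise here.
warnings.filterwarnings("ignore", message=".*calibrator step ratio.*")


@pytest.fixture(scope="session")
def clean_run():
    """Noise-free 11-point 3-fold series; the fit must recover truth exactly."""
    return generate_run(SimScenario(cq_noise_sd=0.0, seed=0))


@pytest.fixture(scope="session")
def clean_fit(clean_run):
    return fit_3pl(clean_run)


@pytest.fixture(scope="session")
def noisy_run():
    """Typical replicate noise (0.2 Cq), NTC with background signal."""
    return generate_run(
        SimScenario(cq_noise_sd=0.2, seed=7, ntc_mode=("determined", 35.0, 0.3))
    )


@pytest.fixture(scope="session")
def noisy_fit(noisy_run):
    return fit_3pl(noisy_run)
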