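import numpy as np
import pytest

from printopt.synthetic import (FactorLevels, ResponseSurface,
                                generate_full_factorial, sample_measurements)


@pytest.fixture(scope="session")
def default_surface():
    return ResponseSurface()


@pytest.fixture(scope="session")
def factorial_design():
    return generate_full_factorial(FactorLevels())


@pytest.fixture(scope="session")
def study_dataset(default_surface, factorial_design):
    """The 81 x 5 = 405-row replicate table of the desk-scale study."""
    return sample_measurements(default_surface, factorial_design,
                               replicates=5, seed=2024)
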