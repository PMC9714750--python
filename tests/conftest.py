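import numpy as np
import pytest

from phosdyn import (
    AcquisitionSpec,
    LifetimeMixture,
    TwoStateParams,
    default_plateau_mixture,
)

# Published two-state parameters for Zn-substituted adult hemoglobin:
# (delta_E kJ/mol, delta_S J/(mol K), K_d, printed T_MP K, printed T_MP SD K)
PUBLISHED_PARAMS = {
    "stripped": (113.4, 526.0, 2.0, 213.1, 0.3),
    "Cl": (97.7, 442.0, 5.3, 214.2, 0.7),
    "IHP": (77.4, 329.0, 31.5, 216.4, 0.4),
    "DPG": (71.5, 299.0, 29.4, 218.5, 0.6),
    "BZF": (42.3, 163.0, 17.8, 225.9, 2.5),
}

TAU0_STRIPPED_MS = 28.7


@pytest.fixture
def stripped_params() -> TwoStateParams:
    dE, dS, Kd, _, _ = PUBLISHED_PARAMS["stripped"]
    return TwoStateParams(dE, dS, Kd, TAU0_STRIPPED_MS)


@pytest.fixture
def plateau_mixture() -> LifetimeMixture:
    return default_plateau_mixture(TAU0_STRIPPED_MS)


@pytest.fixture
def small_acq() -> AcquisitionSpec:
    """A short, cheap acquisition for Monte-Carlo checks."""
    return AcquisitionSpec(bin_width=0.08, n_bins=200, n_flashes=14000,
                           counts_per_flash_scale=0.1)


@pytest.fixture
def transition_grid() -> np.ndarray:
    """5 K sampling through the activation region."""
    return np.arange(185.0, 246.0, 5.0)
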