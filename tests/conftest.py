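import numpy as np
import pytest

from rad51quant import AcquisitionParams, StrainDesign, default_strain_designs


@pytest.fixture(scope="session")
def acq():
    """Default acquisition geometry (noisy sCMOS model)."""
    return AcquisitionParams()


@pytest.fixture(scope="session")
def acq_noise_free():
    return AcquisitionParams(poisson=False, read_noise_sd=0.0)


@pytest.fixture(scope="session")
def designs():
    return default_strain_designs(3)


def straight_filament_design(length_px: float, photons: float = 50_000.0) -> StrainDesign:
    """A degenerate design planting one straight filament of fixed length."""
    return StrainDesign(
        name="probe",
        category_probs={"simple": 1.0},
        filament_length_px=(length_px, 1e-9, length_px - 0.01, length_px + 0.01),
        filament_photons=(photons, 1e-9),
        max_bow_frac=0.0,
    )


def single_focus_design(photons: float = 8_000.0) -> StrainDesign:
    return StrainDesign(
        name="probe",
        category_probs={"foci_only": 1.0},
        foci_count_mean=0.0,  # max(1, Poisson(0)) -> exactly one focus
        focus_photons=(photons, 1e-9),
    )
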