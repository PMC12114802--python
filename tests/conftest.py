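import numpy as np
import pytest

import fluoropk as fp


@pytest.fixture(scope="session")
def substance():
    return fp.default_substance()


@pytest.fixture(scope="session")
def phys73():
    return fp.default_physiology(73.0)


@pytest.fixture(scope="session")
def phys49():
    return fp.default_physiology(49.0)


@pytest.fixture(scope="session")
def erroneous_profile(phys49):
    """The index patient's erroneously administered schedule: 3052 mg / 2 h."""
    return fp.simulate_to_washout(fp.DosingRegimen.infusion(3052.0, 2.0), phys49)


@pytest.fixture(scope="session")
def planned_profile(phys49):
    """The index patient's planned schedule: 4612 mg / 24 h."""
    return fp.simulate_to_washout(fp.DosingRegimen.infusion(4612.0, 24.0), phys49)


def make_profile(time_h, c_venous, regimen) -> fp.ConcentrationTimeProfile:
    """Hand-built profile for metric unit tests (tissues zeroed)."""
    time_h = np.asarray(time_h, dtype=float)
    c_venous = np.asarray(c_venous, dtype=float)
    return fp.ConcentrationTimeProfile(
        time_h=time_h,
        c_venous=c_venous,
        c_arterial=c_venous.copy(),
        c_tissue=np.zeros((len(time_h), 1)),
        tissue_names=("liver",),
        amount_metabolized_mg=np.zeros(len(time_h)),
        regimen=regimen,
    )
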