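import warnings

import numpy as np
import pytest

from confsel.rdc import SaupeTensor
from confsel.shifts import load_random_coil_table
from confsel.synthetic import PeptideSpec, build_two_helix_peptide


@pytest.fixture(scope="session")
def spec():
    return PeptideSpec()


@pytest.fixture(scope="session")
def bound_peptide(spec):
    """Two-helix peptide at the reference interhelical angle (built once)."""
    return build_two_helix_peptide(spec, rng_seed=0)


@pytest.fixture(scope="session")
def rotated_peptide():
    """Same peptide rebuilt with the interhelical angle rotated by ~90 deg."""
    return build_two_helix_peptide(PeptideSpec(target_theta=44.0), rng_seed=0)


@pytest.fixture(scope="session")
def rc_table():
    return load_random_coil_table()


@pytest.fixture(scope="session")
def generator_tensor():
    return SaupeTensor.from_parameters(da=8.0, rhombicity=0.3, euler_zyz_deg=(20.0, 40.0, 60.0))


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


def random_tensor(rng: np.random.Generator, scale: float = 10.0) -> SaupeTensor:
    """Random symmetric traceless tensor (shared test helper)."""
    v = rng.normal(0.0, scale, size=5)
    return SaupeTensor.from_elements(*v)
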