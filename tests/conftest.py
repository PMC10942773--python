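import numpy as np
import pytest

from isoresp.isotopes import IsotopeMeasurement
from isoresp.mixing import Endmember, EndmemberSet


@pytest.fixture(scope="session")
def endmembers() -> EndmemberSet:
    """A well-separated three-pool mixing triangle (synthetic signatures)."""
    return EndmemberSet(
        [
            Endmember(
                "phytoplankton",
                IsotopeMeasurement(-20.0, 50.0, sigma_delta13C=1.0, sigma_Delta14C=50.0),
            ),
            Endmember(
                "acetate_ferm",
                IsotopeMeasurement(-38.0, -250.0, sigma_delta13C=1.0, sigma_Delta14C=50.0),
            ),
            Endmember(
                "pre_aged",
                IsotopeMeasurement(-27.0, -900.0, sigma_delta13C=1.0, sigma_Delta14C=50.0),
            ),
        ]
    )


@pytest.fixture(scope="session")
def exact_endmembers() -> EndmemberSet:
    """Same triangle with zero signature uncertainty (deterministic geometry)."""
    return EndmemberSet(
        [
            Endmember("phytoplankton", IsotopeMeasurement(-20.0, 50.0)),
            Endmember("acetate_ferm", IsotopeMeasurement(-38.0, -250.0)),
            Endmember("pre_aged", IsotopeMeasurement(-27.0, -900.0)),
        ]
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
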