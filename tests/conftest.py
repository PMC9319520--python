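import numpy as np
import pytest

from dermakin import PKParams, SkinTransportParams
from dermakin.synthetic_data import nortriptyline_fixtures

#: in vitro Franz-cell sampling schedule of the nortriptyline study, h
INVITRO_SCHEDULE = np.array([3, 5, 7, 9, 24, 26, 28, 30], dtype=float)
#: in vivo blood-sampling schedule, h
INVIVO_SCHEDULE = np.array([8, 12, 24, 27, 30, 46, 48, 51, 54], dtype=float)


@pytest.fixture(scope="session")
def fixtures():
    return nortriptyline_fixtures(seed=0)


@pytest.fixture(scope="session")
def invitro_params() -> SkinTransportParams:
    """Fitted infinite-dose skin parameters of the study."""
    return SkinTransportParams(R0=229.0, kout=0.10, CD=50000.0, S=1.45)


@pytest.fixture(scope="session")
def finite_params() -> SkinTransportParams:
    """Finite-dose parameters (in vivo kin, in vitro kout)."""
    return SkinTransportParams(kin=0.065, kout=0.10, Q0=100.0)


@pytest.fixture(scope="session")
def iv_pk() -> PKParams:
    """IV-study two-compartment disposition parameters."""
    return PKParams(CL=1580.0, V1=488.0, VT=1568.0, CLic=3340.0)


@pytest.fixture(scope="session")
def invivo_pk() -> PKParams:
    """Disposition with clearance replaced by the percutaneous CL_app."""
    return PKParams(CL=3126.0, V1=488.0, VT=1568.0, CLic=3340.0)
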