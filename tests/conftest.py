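import numpy as np
import pytest

from bclscreen.sprkin import InjectionSchedule, KineticParams, build_schedule


@pytest.fixture(scope="session")
def faststep() -> InjectionSchedule:
    return build_schedule("faststep_bcl2")


@pytest.fixture(scope="session")
def two_site_params() -> KineticParams:
    """Ground truth in the submicromolar/micromolar range typical of the assay."""
    return KineticParams(ka=(1e5, 5e4), kd=(0.019, 0.05), rmax=(60.0, 40.0))


@pytest.fixture(scope="session")
def one_site_params() -> KineticParams:
    return KineticParams(ka=(2e5,), kd=(0.04,), rmax=(80.0,))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
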