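import numpy as np
import pytest

from saturn import (
    TissueParams,
    build_saturn_protocol,
    simulate_acquisition,
)


@pytest.fixture(scope="session")
def default_protocol():
    """Clinical default: 60 bpm, 4 s rest periods."""
    return build_saturn_protocol(heart_rate=60)


@pytest.fixture(scope="session")
def baseline_protocol():
    """Simulation baseline: 60 bpm with 10 s rest to suppress incomplete
    recovery as a confounder."""
    return build_saturn_protocol(heart_rate=60, rest_period=10_000)


@pytest.fixture(scope="session")
def myocardium():
    return TissueParams(T1=1573.0, T2=33.2, T2star=25.3)


@pytest.fixture(scope="session")
def midrange_tissue():
    return TissueParams(T1=1500.0, T2=50.0, T2star=25.0)


@pytest.fixture(scope="session")
def clean_series(baseline_protocol, midrange_tissue):
    return simulate_acquisition(baseline_protocol, midrange_tissue)
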