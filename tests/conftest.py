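import numpy as np
import pytest

from biophyskit.spr_kinetics import (
    CIB2_A7BM_MG,
    InjectionProtocol,
    RateConstants,
)


@pytest.fixture
def mg_constants() -> RateConstants:
    """Published bivalent constants for the Mg2+-only condition."""
    return CIB2_A7BM_MG


@pytest.fixture
def protocol() -> InjectionProtocol:
    """Standard 120 s / 200 s injection cycle at 1 s sampling."""
    return InjectionProtocol(analyte_concentration=30e-6)


@pytest.fixture
def short_protocol() -> InjectionProtocol:
    """Abbreviated cycle for fit tests that do not need the full trace."""
    return InjectionProtocol(analyte_concentration=30e-6,
                             t_association=60.0, t_dissociation=60.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
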