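import numpy as np
import pytest

from axregen import (
    PhaseLengthParams,
    PhaseLengths,
    RecruitmentSignal,
    SimConfig,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def long_lengths():
    """Deterministic long-regime durations equal to the tabulated means."""
    return PhaseLengths(152.0, 179.0, 9.0)


@pytest.fixture
def short_lengths():
    return PhaseLengths(22.0, 88.0, 9.0)


@pytest.fixture
def deterministic_long():
    """Long-regime parameters with zero spread (degenerate lognormals)."""
    return PhaseLengthParams(152.0, 0.0, 179.0, 0.0, 9.0, 0.0)


@pytest.fixture
def deterministic_short():
    return PhaseLengthParams(22.0, 0.0, 88.0, 0.0, 9.0, 0.0)


@pytest.fixture
def best_fit_config():
    """The reported best-fitting parametrization of the regenerating cord."""
    return SimConfig(n0=196, signal=RecruitmentSignal(lam=828.0, tau=85.0))
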