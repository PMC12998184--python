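import numpy as np
import pytest

from gutnitro import AbioticModelParams, ConsumptionModelParams, GrowthModelParams


@pytest.fixture
def no_decay_abiotic():
    """Standard assay cysteine (1.5 mM) but no pH-driven decay channel."""
    return AbioticModelParams(background_decay_per_h=0.0)


@pytest.fixture
def zero_abiotic():
    return AbioticModelParams.zero()


@pytest.fixture
def hourly_times():
    return np.arange(0.0, 24.1, 0.5)


@pytest.fixture
def fig_growth():
    """Growth parameters of a nitrite-insensitive gut organism: lag 5 h,
    doubling time 1.1 h, maximum OD 0.6."""
    return GrowthModelParams(od_initial=0.05, od_max=0.6, mu_max=np.log(2) / 1.1, lag=5.0)


@pytest.fixture
def zero_order_consumption():
    """Saturating-regime depletion: a = 100 umol/gDW/h, km = 0."""
    return ConsumptionModelParams(specific_activity=100.0, km=0.0, biomass_per_od=0.36)
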