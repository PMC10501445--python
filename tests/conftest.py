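import numpy as np
import pandas as pd
import pytest

from sclc_cea import ModelParams, RiskTable, preprocess_curve
from sclc_cea.model import CostEffectivenessModel


@pytest.fixture(scope="session")
def base_params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def base_model() -> CostEffectivenessModel:
    """Median-calibrated Weibull model at base-case inputs (shared: read-only)."""
    return CostEffectivenessModel.from_medians()


@pytest.fixture()
def toy_curve():
    return preprocess_curve([(0, 1.0), (1, 0.75), (2, 0.5)])


@pytest.fixture()
def toy_risk():
    return RiskTable([0, 1, 2], [4, 3, 2])


@pytest.fixture()
def all_event_ipd():
    rng = np.random.default_rng(123)
    t = rng.weibull(1.2, size=400) * 8.0
    return pd.DataFrame({"time_months": t, "event": 1})
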