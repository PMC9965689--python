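import pytest

from frostprobe.calibration import CalibrationModel
from frostprobe.core_model import ProbePhysics

# Published per-species calibration lines (slope %/V, intercept %, R^2).
TABLE_MODELS = {
    "juniperus": dict(slope_k=31.28, intercept_b=-6.13, r_squared=0.9845),
    "lagerstroemia": dict(slope_k=52.27, intercept_b=-30.97, r_squared=0.9803),
    "pachira": dict(slope_k=49.11, intercept_b=-12.63, r_squared=0.9892),
}


@pytest.fixture
def juniperus_model() -> CalibrationModel:
    return CalibrationModel(species="juniperus", **TABLE_MODELS["juniperus"])


@pytest.fixture
def pachira_model() -> CalibrationModel:
    return CalibrationModel(species="pachira", **TABLE_MODELS["pachira"])


@pytest.fixture
def unit_physics() -> ProbePhysics:
    """Physics with unit gain for hand-checkable reflection arithmetic."""
    return ProbePhysics(beta0=1.0, A=1.0)
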