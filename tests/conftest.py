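import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from oacea import knee_oa  # noqa: E402


@pytest.fixture(scope="session")
def knee_model():
    """The bundled, calibrated knee-OA model."""
    return knee_oa.load("knee_oa_2020")


@pytest.fixture()
def toy_linear_config():
    """Minimal two-strategy model with delta_cost(x) = 100 - 2x."""
    return {
        "name": "toy_linear",
        "parameters": [
            {"name": "x", "base": 10.0, "low": 0.0, "high": 100.0, "role": "cost"},
        ],
        "tree": {
            "kind": "decision",
            "label": "root",
            "children": [
                {"node": {"kind": "terminal", "label": "new",
                          "cost": "600", "effect": 0.6}},
                {"node": {"kind": "terminal", "label": "standard",
                          "cost": "500 + 2*x", "effect": 0.4}},
            ],
        },
        "strategies": ["new", "standard"],
    }
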