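import hypothesis
import numpy as np
import pytest

from rtcycle import ModelParams, get_preset

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def fig4() -> ModelParams:
    """All rates equal, v- = 0.9 v+, D = 0.2: the moment/ISF benchmark set."""
    return get_preset("fig4").params


@pytest.fixture(scope="session")
def fig4_equal() -> ModelParams:
    return get_preset("fig4_equal").params


@pytest.fixture(scope="session")
def fig8() -> ModelParams:
    """Pattern-formation regime used for separatrix and state-diagram scans."""
    return get_preset("fig8").params


@pytest.fixture(scope="session")
def fig9() -> ModelParams:
    """fig8 regime with v+ = 2 v- = 0.1: traveling waves."""
    return get_preset("fig9").params
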