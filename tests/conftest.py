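import numpy as np
import pytest

from agbmap.features import assemble_feature_stack, extract_features
from agbmap.synthetic import ScenarioConfig, build_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """64 x 64 landscape (100 systematic plots) shared across tests."""
    cfg = ScenarioConfig(n_rows=64, n_cols=64)
    return build_scenario(cfg, seed=7)


@pytest.fixture(scope="session")
def small_feature_table(small_scenario):
    fstack = assemble_feature_stack(small_scenario.stack)
    return extract_features(fstack, small_scenario.plots)


@pytest.fixture(scope="session")
def default_scenario():
    """Default-configuration landscape (128 x 128, 400 plots)."""
    return build_scenario(seed=11)


def rel_err(a, b):
    return abs(a - b) / max(abs(b), 1e-12)


@pytest.fixture
def relerr():
    return rel_err
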