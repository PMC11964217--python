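import numpy as np
import pytest

from sleepsem import default_config, generate_panel
from sleepsem.sleepmetrics import derive_sleep_facets


def small_config(n=300):
    cfg = default_config()
    cfg.n_per_group = {"boy": n, "girl": n}
    return cfg


@pytest.fixture(scope="session")
def default_panel():
    """One complete panel at the calibrated study size (shared, read-only)."""
    return generate_panel(default_config(), seed=12345)


@pytest.fixture(scope="session")
def default_panel_facets(default_panel):
    return derive_sleep_facets(default_panel)


@pytest.fixture(scope="session")
def small_panel():
    """A small complete panel for fast structural tests."""
    return generate_panel(small_config(500), seed=777)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
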