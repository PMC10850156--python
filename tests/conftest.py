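import numpy as np
import pandas as pd
import pytest

from fiberbehav.config import SessionConfig
from fiberbehav.io_formats import EventTable


@pytest.fixture
def config() -> SessionConfig:
    return SessionConfig()


@pytest.fixture
def short_config() -> SessionConfig:
    """Config with a short z-score window for fast small-trace tests."""
    return SessionConfig(zscore_window=10.0)


def make_events(rows) -> EventTable:
    return EventTable(pd.DataFrame(rows, columns=["behavior", "start", "stop"]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
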