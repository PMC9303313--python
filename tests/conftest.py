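import numpy as np
import pytest

from gapmertox import parse_gapmer
from gapmertox.datasets import hepatotoxic_screen_table


@pytest.fixture
def ts1():
    """The most hepatotoxic gapmer of the screening table, 2-10-2 design."""
    return parse_gapmer("TS1", "GTTATGCCACCCTA")


@pytest.fixture
def screen_table():
    return hepatotoxic_screen_table()


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
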