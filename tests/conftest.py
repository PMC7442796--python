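import sys
from pathlib import Path

import numpy as np
import pytest

# make the experiment library in scripts/ importable from the test suite
sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "scripts"))

from canidiv.fossilrec import SpeciesRange, TimeScale


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def default_scale():
    return TimeScale()


@pytest.fixture
def simple_scale():
    """Four equal 10-My intervals over 40 My."""
    return TimeScale(edges=(40.0, 30.0, 20.0, 10.0, 0.0))


@pytest.fixture
def toy_ranges():
    return [
        SpeciesRange("early", ts=38.0, te=31.0),
        SpeciesRange("lazarus", ts=35.0, te=5.0),
        SpeciesRange("recent", ts=12.0, te=0.0),  # extant
        SpeciesRange("single", ts=25.0, te=25.0),
    ]
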