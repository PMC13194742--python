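import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the test-only FD oracle

from hydrostim.dielectrics import TissueMedium, default_table


@pytest.fixture(scope="session")
def hydrogel():
    return TissueMedium("hydrogel", conductivity=30.0, relative_permittivity=1.35)


@pytest.fixture(scope="session")
def brain():
    return TissueMedium("brain", conductivity=0.27, relative_permittivity=670.0)


@pytest.fixture(scope="session")
def table():
    return default_table()
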