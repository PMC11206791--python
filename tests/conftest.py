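import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from hmoscreen.catalog import default_catalog
from hmoscreen.rules import default_rules


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def ruleset(catalog):
    return default_rules(catalog)
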