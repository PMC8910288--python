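import pytest

from refmem.components import STANDARD_CONTRASTS
from refmem.io import packaged_sequence


@pytest.fixture(scope="session")
def contrasts():
    return {c.name: c for c in STANDARD_CONTRASTS}


@pytest.fixture(scope="session")
def protein_sequence():
    """Synthetic stand-in sequence for the truncated human enzyme construct."""
    return packaged_sequence()
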