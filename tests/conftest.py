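import pytest

from rdnarray.kmeralign import BuiltinAligner
from rdnarray.simdata import make_synthetic_reference


@pytest.fixture(scope="session")
def ref():
    """One synthetic repeat unit shared across the suite (fixed seed)."""
    return make_synthetic_reference(seed=1)


@pytest.fixture(scope="session")
def aligner(ref):
    return BuiltinAligner(ref)
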