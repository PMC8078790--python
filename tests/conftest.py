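import numpy as np
import pytest

import nickseq as nk
from nickseq.consensus import default_layout


@pytest.fixture(scope="session")
def amplicon():
    return nk.default_amplicon()


@pytest.fixture(scope="session")
def site(amplicon):
    return nk.default_site(amplicon)


@pytest.fixture(scope="session")
def window(site, amplicon):
    return nk.scoring_window(site, 65, amplicon)


@pytest.fixture(scope="session")
def layout(amplicon):
    return default_layout(amplicon)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_call(events=(), key=("A" * 10, "C" * 10), **kw):
    """Hand-built molecule call for profiler unit tests."""
    from nickseq.calling import MoleculeCall

    return MoleculeCall(key=key, family_size=3, events=tuple(events), **kw)


@pytest.fixture()
def call_factory():
    return make_call
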