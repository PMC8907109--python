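import pytest
from hypothesis import settings

from adductms import OligoSequence, PeptideSequence

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def s1():
    return OligoSequence("GTATTGGCACGTA", name="S1")


@pytest.fixture(scope="session")
def s1c():
    return OligoSequence("TACGTGCCAATAC", name="S1c")


@pytest.fixture(scope="session")
def p1():
    return PeptideSequence("VLEYLTAEILE", name="P1")


@pytest.fixture(scope="session")
def p2():
    return PeptideSequence("SKAMGIMNSFVNDIFERIAGEASRLAHY", name="P2")
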