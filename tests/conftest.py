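import pytest

from molae.chemio import EOS, PAD, SOS, Vocabulary
from molae.fixtures import FixtureSpec, generate_molecules


@pytest.fixture(scope="session")
def small_vocab() -> Vocabulary:
    return Vocabulary((PAD, SOS, EOS, "(", ")", "1", "=", "C", "N", "O"))


@pytest.fixture(scope="session")
def corpus20():
    """Small synthetic corpus shared by model/training tests."""
    return generate_molecules(FixtureSpec(20, 3, 12, seed=5))


@pytest.fixture(scope="session")
def corpus50():
    """The memorization corpus: 50 molecules of at most 15 SELFIES tokens."""
    return generate_molecules(FixtureSpec(50, 3, 15, seed=11))
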