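import pytest

from microtraits.fixtures import generate_corpus, generate_term_lists
from microtraits.preprocess import annotate_sentence


@pytest.fixture(scope="session")
def term_lists():
    return generate_term_lists()


@pytest.fixture(scope="session")
def small_corpus():
    """10 synthetic taxa, all templates, no distractors."""
    return generate_corpus(10, seed=7, noise=0.0)


@pytest.fixture
def annotate():
    return lambda text: annotate_sentence(text)
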