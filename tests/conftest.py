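import pytest

from famhx.preprocess import preprocess
from famhx.rules import load_cue_lexicon, load_family_lexicon
from famhx.synthetic import GenConfig, generate_corpus


@pytest.fixture(scope="session")
def lexicon():
    return load_family_lexicon()


@pytest.fixture(scope="session")
def cues():
    return load_cue_lexicon()


@pytest.fixture(scope="session")
def small_corpus():
    """30 generated documents with gold entities and relations."""
    return generate_corpus(GenConfig(n_documents=30, seed=5))


@pytest.fixture(scope="session")
def tiny_corpus():
    return generate_corpus(GenConfig(n_documents=10, seed=17))


def sentence_of(text: str):
    return preprocess(text, "doc").sentences[0]


@pytest.fixture
def make_sentence():
    return sentence_of
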