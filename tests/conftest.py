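import pytest

from mutrelex.search import build_index
from mutrelex.synthetic import GeneratorConfig, generate


@pytest.fixture(scope="session")
def default_data():
    """The default synthetic study conditions: corpus, truth, background."""
    return generate(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def default_corpus(default_data):
    return default_data[0]


@pytest.fixture(scope="session")
def default_truth(default_data):
    return default_data[1]


@pytest.fixture(scope="session")
def default_index(default_data):
    return build_index(default_data[2])


@pytest.fixture(scope="session")
def sentence_data():
    """A larger corpus sized for sentence-level training."""
    return generate(GeneratorConfig(seed=23, n_documents=400))
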