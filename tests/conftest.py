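import pytest

from mrim.synth import GeneratorSpec, generate_corpus, generate_lexicons


@pytest.fixture(scope="session")
def lexicons():
    return generate_lexicons(seed=0)


@pytest.fixture(scope="session")
def resources(lexicons):
    return lexicons.extraction_resources()


@pytest.fixture(scope="session")
def small_spec():
    return GeneratorSpec(n=400, seed=7)


@pytest.fixture(scope="session")
def small_corpus(small_spec, lexicons):
    corpus, truth = generate_corpus(small_spec, lexicons)
    return corpus, truth
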