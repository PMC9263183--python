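import pytest

from litpath import annotate_corpus, default_lexicons, filter_corpus
from litpath.synth import CorpusConfig, gen_corpus


@pytest.fixture(scope="session")
def lexicons():
    return default_lexicons()


@pytest.fixture(scope="session")
def small_corpus():
    """300-record synthetic corpus with its ground truth (seed 1)."""
    return gen_corpus(CorpusConfig(n=300), seed=1)


@pytest.fixture(scope="session")
def annotated_small(small_corpus, lexicons):
    records, truth = small_corpus
    survivors, report = filter_corpus(records, lexicons.negative)
    result = annotate_corpus(survivors, lexicons)
    return survivors, truth, result, report


@pytest.fixture(scope="session")
def medium_corpus(lexicons):
    """4,000-record corpus used by rank-stability property tests."""
    records, truth = gen_corpus(CorpusConfig(n=4000), seed=11)
    survivors, _ = filter_corpus(records, lexicons.negative)
    result = annotate_corpus(survivors, lexicons)
    return survivors, truth, result
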