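import pytest

import litcohesion as lc


@pytest.fixture(scope="session")
def topic_spec():
    return lc.CorpusSpec(
        n_genes=240,
        n_topics=24,
        vocab_per_topic=40,
        background_vocab=40,
        background_mix=0.15,
        abstracts_family="lognormal",
        abstracts_median=4.0,
        abstracts_sigma=0.8,
        words_per_abstract=25.0,
        promiscuous_citations=4,
        seed=20240501,
    )


@pytest.fixture(scope="session")
def topic_corpus(topic_spec):
    return lc.generate_corpus(topic_spec)


@pytest.fixture(scope="session")
def documents(topic_corpus):
    abstracts, links, _ = topic_corpus
    docs, _ = lc.build_corpus(abstracts, links)
    return docs


@pytest.fixture(scope="session")
def fitted(documents):
    return lc.fit_from_documents(documents)


@pytest.fixture(scope="session")
def model(fitted):
    return fitted[0]


@pytest.fixture(scope="session")
def tgm(fitted):
    return fitted[1]


@pytest.fixture(scope="session")
def similarity(model):
    return lc.similarity_matrix(model)


@pytest.fixture(scope="session")
def calibration(similarity):
    return lc.calibrate_threshold(
        similarity, n_sets=100, size_range=(10, 30), percentile=95, seed=11
    )
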