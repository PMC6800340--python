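import numpy as np
import pytest

from semrsa import rdm as R
from semrsa import synth as S
from semrsa import topics as T


def matched_topic_r(model: T.TopicModel, truth: T.TopicModel) -> float:
    """Mean Pearson r between fitted and planted topic-word rows after
    optimal one-to-one topic matching (restricted to the fitted vocabulary)."""
    from scipy.optimize import linear_sum_assignment
    cols = [truth.vocabulary.index(w) for w in model.vocabulary]
    A = model.topic_word
    B = truth.topic_word[:, cols]
    C = np.corrcoef(np.vstack([A, B]))[:model.K, model.K:]
    C = np.nan_to_num(C)
    ri, ci = linear_sum_assignment(-C)
    return float(C[ri, ci].mean())


@pytest.fixture(scope="session")
def planted_corpus():
    """A small planted topic model plus a corpus sampled from it."""
    truth = S.generate_topic_ground_truth(K=5, V=50, concentration=0.05, seed=1)
    cooc, thetas = S.generate_cooccurrence(
        truth, n_verbs=100, tokens_per_verb=2000, verb_concentration=0.05,
        seed=2)
    return truth, cooc, thetas


@pytest.fixture(scope="session")
def fitted_model(planted_corpus):
    truth, cooc, _ = planted_corpus
    docs = T.build_verb_documents(cooc)
    return T.fit_topic_model(docs, K=5, seed=0)


@pytest.fixture(scope="session")
def small_stimuli(planted_corpus):
    truth, cooc, _ = planted_corpus
    return S.generate_stimulus_set(n_sets=5, seed=3, verbs=cooc.verbs,
                                   nouns=truth.vocabulary)


@pytest.fixture(scope="session")
def small_model_rdms(planted_corpus, small_stimuli):
    truth, _, _ = planted_corpus
    return R.build_model_rdms(truth, small_stimuli)


def toy_topic_model(topic_word, topic_prior, vocabulary=None):
    topic_word = np.asarray(topic_word, dtype=float)
    K, V = topic_word.shape
    if vocabulary is None:
        vocabulary = [f"n{i}" for i in range(V)]
    m = T.TopicModel(K=K, topic_word=topic_word,
                     topic_prior=np.asarray(topic_prior, dtype=float),
                     vocabulary=vocabulary, informativeness=np.ones(K))
    m.informativeness = T.topic_informativeness(m)
    return m


def random_rdm(n, rng, item_order=None, label="verb_topic"):
    vals = np.abs(rng.standard_normal((n, n)))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 0.0)
    if item_order is None:
        item_order = [f"s{i:04d}" for i in range(n)]
    return R.RDM(vals, item_order, label, "cosine")
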