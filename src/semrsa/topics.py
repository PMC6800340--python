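"""Latent-topic semantic space for verbs and their direct-object nouns.

A verb's selectional preferences are modelled by treating each verb as a
"document" containing the direct-object (DO) nouns it co-occurs with in a
large corpus, repeated in proportion to an association weight (e.g. local
mutual information).  Fitting latent Dirichlet allocation (LDA) to these
verb documents yields K latent topics, each a distribution over the noun
vocabulary, P(noun | topic).  From the fitted model we derive:

* the **verb topic vector** P(topic | verb) — the verb document's fitted
  topic mixture, expressing the semantic constraints the verb places on an
  upcoming DO noun;
* the **noun topic vector** P(topic | noun), obtained by Bayes inversion
  P(topic | noun) ∝ P(noun | topic) · P(topic), expressing the
  context-independent semantics of the noun in the same topic space;
* the **verb-weighted noun vector**, the element-wise product of the two,
  retaining only topics preferred by both verb and noun — a model of the
  noun's meaning under the verb's constraints;
* **topic entropy** H(v) = −Σ_k p_k ln p_k, the (inverse) strength of a
  verb's constraint: a verb concentrated on few topics constrains strongly;
* **verb constraint error**, the cosine distance between verb and noun
  topic vectors — how hard the noun is to fit into the verb's constraints.

Because topics differ in how semantically dispersed they are, an optional
per-topic *informativeness* weight (the normalized entropy deficit of the
topic's word distribution) can be applied to topic-vector loadings before
any downstream quantity is computed.

All logarithms are natural; entropies are in nats.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from sklearn.decomposition import LatentDirichletAllocation

__all__ = [
    "CooccurrenceTable",
    "TopicModel",
    "TopicVector",
    "DegenerateInputError",
    "UnknownItemError",
    "build_verb_documents",
    "fit_topic_model",
    "verb_topic_vector",
    "noun_topic_vector",
    "topic_informativeness",
    "apply_informativeness",
    "topic_entropy",
    "verb_weighted_noun_vector",
    "cosine_distance",
    "constraint_error",
]

log = logging.getLogger(__name__)

_NORM_TOL = 1e-9


class DegenerateInputError(ValueError):
    """An input (zero vector, zero-probability item, ...) admits no answer."""


class UnknownItemError(KeyError):
    """A verb or noun token is not part of the fitted model."""


# ---------------------------------------------------------------------------
# Co-occurrence table


@dataclass
class CooccurrenceTable:
    """Sparse verb × noun nonnegative association weights.

    ``table`` has columns ``verb``, ``noun``, ``weight``.  Weights are
    nonnegative reals (raw counts or LMI-style association scores); there
    is at most one row per (verb, noun) pair.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"verb", "noun", "weight"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"co-occurrence table needs columns {sorted(required)}")
        if len(self.table) == 0:
            raise ValueError("empty co-occurrence table")
        w = np.asarray(self.table["weight"], dtype=float)
        if not np.all(np.isfinite(w)) or (w < 0).any():
            raise ValueError("co-occurrence weights must be finite and nonnegative")
        if self.table.duplicated(subset=["verb", "noun"]).any():
            raise ValueError("duplicate (verb, noun) pairs in co-occurrence table")

    @property
    def verbs(self) -> list[str]:
        return sorted(self.table["verb"].unique())

    @property
    def nouns(self) -> list[str]:
        return sorted(self.table["noun"].unique())

    @classmethod
    def from_tsv(cls, path) -> "CooccurrenceTable":
        """Read a 3-column TSV ``verb<TAB>noun<TAB>weight`` (header optional)."""
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment=None)
        if df.shape[1] != 3:
            raise ValueError("expected exactly 3 tab-separated columns")
        first = df.iloc[0, 2]
        try:
            float(first)
        except (TypeError, ValueError):
            df = df.iloc[1:].reset_index(drop=True)
        df.columns = ["verb", "noun", "weight"]
        df["weight"] = df["weight"].astype(float)
        return cls(df)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False,
                          columns=["verb", "noun", "weight"])


def build_verb_documents(cooc: CooccurrenceTable,
                         rounding: str = "half_up") -> dict[str, dict[str, int]]:
    """Turn weighted co-occurrences into per-verb bag-of-noun count documents.

    Each DO noun appears in its verb's document N times, where N is the
    (rounded) association weight.  Real-valued weights are rounded half-up
    by default; verbs whose document rounds to empty are dropped with a
    warning.
    """
    if rounding not in ("half_up", "floor", "ceil"):
        raise ValueError(f"unknown rounding mode {rounding!r}")
    docs: dict[str, dict[str, int]] = {}
    for verb, sub in cooc.table.groupby("verb", sort=True):
        doc: dict[str, int] = {}
        for noun, weight in zip(sub["noun"], sub["weight"]):
            if rounding == "half_up":
                n = math.floor(weight + 0.5)
            elif rounding == "floor":
                n = math.floor(weight)
            else:
                n = math.ceil(weight)
            if n > 0:
                doc[noun] = n
        if doc:
            docs[str(verb)] = doc
        else:
            log.warning("verb %r dropped: document empty after rounding", verb)
    if not docs:
        raise ValueError("all verb documents empty after rounding")
    return docs


# ---------------------------------------------------------------------------
# Topic model


@dataclass
class TopicModel:
    """A fitted K-topic model over a DO-noun vocabulary.

    ``topic_word`` is row-stochastic: row k is P(noun | topic k).
    ``topic_prior`` is P(topic), the corpus-weighted mean of per-document
    topic mixtures.  ``doc_topic`` maps each training verb to its fitted
    P(topic | verb).  ``informativeness`` holds per-topic weights in [0, 1]
    (normalized entropy deficit of the topic's word distribution).
    """

    K: int
    topic_word: np.ndarray
    topic_prior: np.ndarray
    vocabulary: list[str]
    informativeness: np.ndarray
    doc_topic: dict[str, np.ndarray] = field(default_factory=dict)
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.topic_word = np.asarray(self.topic_word, dtype=float)
        self.topic_prior = np.asarray(self.topic_prior, dtype=float)
        self.informativeness = np.asarray(self.informativeness, dtype=float)
        K, V = self.topic_word.shape
        if K != self.K or V != len(self.vocabulary):
            raise ValueError("topic_word shape inconsistent with K / vocabulary")
        if np.abs(self.topic_word.sum(axis=1) - 1.0).max() > _NORM_TOL:
            raise ValueError("topic_word rows must sum to 1")
        if abs(self.topic_prior.sum() - 1.0) > _NORM_TOL:
            raise ValueError("topic_prior must sum to 1")
        if (self.informativeness < 0).any() or not (self.informativeness > 0).any():
            raise ValueError("informativeness must be >= 0 with a positive entry")
        self._vocab_index = {w: i for i, w in enumerate(self.vocabulary)}

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            g = f.create_group("topic_model")
            g.create_dataset("topic_word", data=self.topic_word)
            g.create_dataset("topic_prior", data=self.topic_prior)
            g.create_dataset("informativeness", data=self.informativeness)
            g.create_dataset(
                "vocabulary", data=np.array(self.vocabulary, dtype=object),
                dtype=h5py.string_dtype())
            verbs = sorted(self.doc_topic)
            g.create_dataset("doc_ids", data=np.array(verbs, dtype=object),
                             dtype=h5py.string_dtype())
            g.create_dataset(
                "doc_topic",
                data=np.stack([self.doc_topic[v] for v in verbs])
                if verbs else np.zeros((0, self.K)))
            g.attrs["K"] = self.K
            for key in ("seed", "alpha", "eta", "max_iter", "n_iter", "converged"):
                if key in self.fit_meta and self.fit_meta[key] is not None:
                    g.attrs[key] = self.fit_meta[key]

    @classmethod
    def load(cls, path) -> "TopicModel":
        with h5py.File(path, "r") as f:
            g = f["topic_model"]
            vocab = [s.decode() if isinstance(s, bytes) else str(s)
                     for s in g["vocabulary"][()]]
            doc_ids = [s.decode() if isinstance(s, bytes) else str(s)
                       for s in g["doc_ids"][()]]
            doc_topic_arr = g["doc_topic"][()]
            meta = {k: g.attrs[k] for k in g.attrs if k != "K"}
            return cls(
                K=int(g.attrs["K"]),
                topic_word=g["topic_word"][()],
                topic_prior=g["topic_prior"][()],
                vocabulary=vocab,
                informativeness=g["informativeness"][()],
                doc_topic={v: doc_topic_arr[i] for i, v in enumerate(doc_ids)},
                fit_meta=meta,
            )

    def noun_index(self, noun: str) -> int:
        try:
            return self._vocab_index[noun]
        except KeyError:
            raise UnknownItemError(f"noun {noun!r} not in vocabulary") from None


def fit_topic_model(documents: dict[str, dict[str, int]],
                    K: int,
                    seed: int = 0,
                    alpha: float | None = None,
                    eta: float = 0.01,
                    max_iter: int = 200,
                    n_init: int = 3) -> TopicModel:
    """Fit a K-topic LDA model to per-verb bag-of-noun documents.

    Variational EM in batch mode; deterministic given ``seed``.  Symmetric
    Dirichlet priors default to alpha = 1/K on document-topic mixtures and
    eta = 0.01 on topic-word distributions.  Variational EM is prone to
    local optima in which one planted topic is split across two fitted
    ones, so ``n_init`` random restarts are run (child seeds of ``seed``)
    and the fit with the best evidence lower bound is kept.  P(topic) is
    computed as the token-count-weighted mean of the per-document topic
    mixtures.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not documents:
        raise ValueError("empty corpus")
    if alpha is None:
        alpha = 1.0 / K
    vocab = sorted({noun for doc in documents.values() for noun in doc})
    vidx = {w: i for i, w in enumerate(vocab)}
    doc_ids = sorted(documents)
    counts = np.zeros((len(doc_ids), len(vocab)))
    for d, verb in enumerate(doc_ids):
        for noun, n in documents[verb].items():
            counts[d, vidx[noun]] = n
    if K * len(vocab) > counts.size:
        log.info("K=%d topics exceed corpus degrees of freedom (%d docs x %d nouns)",
                 K, len(doc_ids), len(vocab))

    best = None
    for sub in range(max(1, n_init)):
        cand = LatentDirichletAllocation(
            n_components=K, doc_topic_prior=alpha, topic_word_prior=eta,
            learning_method="batch", max_iter=max_iter,
            random_state=(seed * 1009 + sub) % (2 ** 32),
            evaluate_every=5, perp_tol=1e-3)
        cand.fit(counts)
        bound = cand.score(counts)
        if best is None or bound > best[0]:
            best = (bound, cand)
    lda = best[1]
    doc_topic_raw = lda.transform(counts)
    topic_word = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    doc_topic = doc_topic_raw / doc_topic_raw.sum(axis=1, keepdims=True)

    token_weights = counts.sum(axis=1)
    prior = (doc_topic * token_weights[:, None]).sum(axis=0) / token_weights.sum()
    prior = prior / prior.sum()

    converged = bool(lda.n_iter_ < max_iter)
    if not converged:
        log.warning("LDA did not converge in %d iterations", max_iter)
    model = TopicModel(
        K=K,
        topic_word=topic_word,
        topic_prior=prior,
        vocabulary=vocab,
        informativeness=np.ones(K),  # placeholder, replaced below
        doc_topic={v: doc_topic[i] for i, v in enumerate(doc_ids)},
        fit_meta={"seed": seed, "alpha": alpha, "eta": eta,
                  "max_iter": max_iter, "n_iter": int(lda.n_iter_),
                  "converged": converged},
    )
    model.informativeness = topic_informativeness(model)
    return model


# ---------------------------------------------------------------------------
# Topic vectors and scalar quantities


@dataclass
class TopicVector:
    """A length-K nonnegative loading vector for one verb, noun, or pair.

    ``kind`` is one of ``verb``, ``noun``, ``verb_weighted``.  Normalized
    vectors sum to 1; verb-weighted products are deliberately left
    unnormalized (cosine distance downstream is scale-invariant).  A
    ``degenerate`` vector (identically zero product) is flagged and rejected
    by distance computations.
    """

    loadings: np.ndarray
    kind: str
    item_id: str
    normalized: bool = True
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        if self.loadings.ndim != 1:
            raise ValueError("loadings must be 1-D")
        if (self.loadings < 0).any():
            raise ValueError("loadings must be nonnegative")
        if self.normalized and not self.degenerate:
            if abs(self.loadings.sum() - 1.0) > _NORM_TOL:
                raise ValueError(f"normalized vector for {self.item_id!r} "
                                 "does not sum to 1")

    @property
    def K(self) -> int:
        return self.loadings.size


def verb_topic_vector(model: TopicModel, verb_id: str) -> TopicVector:
    """P(topic | verb): the verb document's fitted topic mixture."""
    try:
        loadings = model.doc_topic[verb_id]
    except KeyError:
        raise UnknownItemError(f"verb {verb_id!r} not in training corpus") from None
    return TopicVector(loadings / loadings.sum(), kind="verb", item_id=verb_id)


def noun_topic_vector(model: TopicModel, noun_id: str) -> TopicVector:
    """P(topic | noun) by Bayes inversion of the topic-word distributions.

    P(topic | noun) ∝ P(noun | topic) · P(topic); the normalizer is the
    noun marginal P(noun) = Σ_k P(noun | k) P(k), which must be positive.
    """
    j = model.noun_index(noun_id)
    joint = model.topic_word[:, j] * model.topic_prior
    marginal = joint.sum()
    if marginal <= 0:
        raise DegenerateInputError(f"noun {noun_id!r} has zero marginal probability")
    return TopicVector(joint / marginal, kind="noun", item_id=noun_id)


def topic_informativeness(model: TopicModel) -> np.ndarray:
    """Per-topic informativeness: normalized entropy deficit over the vocabulary.

    weight_k = (ln V − H(P(·|topic k))) / ln V, clipped at 0.  A topic
    uniform over the vocabulary is uninformative (0); a topic concentrated
    on a single noun is maximally informative (1).
    """
    V = len(model.vocabulary)
    if V == 1:
        return np.ones(model.K)
    H = np.array([_entropy_nats(row) for row in model.topic_word])
    return np.clip((math.log(V) - H) / math.log(V), 0.0, None)


def apply_informativeness(vec: TopicVector, weights: np.ndarray) -> TopicVector:
    """Weight a topic vector's loadings by per-topic informativeness.

    Element-wise multiplication; the result is renormalized iff the input
    vector is flagged normalized.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape != vec.loadings.shape:
        raise ValueError("weight vector length does not match K")
    loadings = vec.loadings * weights
    total = loadings.sum()
    if total <= 0:
        return TopicVector(loadings, kind=vec.kind, item_id=vec.item_id,
                           normalized=False, degenerate=True)
    if vec.normalized:
        loadings = loadings / total
    return TopicVector(loadings, kind=vec.kind, item_id=vec.item_id,
                       normalized=vec.normalized)


def _entropy_nats(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def topic_entropy(vec: TopicVector | np.ndarray) -> float:
    """Shannon entropy (nats) of a topic vector, normalized first.

    0·ln 0 is treated as 0.  The value lies in [0, ln K], attained at
    one-hot and uniform vectors respectively.
    """
    loadings = vec.loadings if isinstance(vec, TopicVector) else np.asarray(vec, float)
    if (loadings < 0).any():
        raise ValueError("loadings must be nonnegative")
    total = loadings.sum()
    if total <= 0:
        raise DegenerateInputError("entropy of an all-zero vector is undefined")
    return _entropy_nats(loadings / total)


def verb_weighted_noun_vector(verb_vec: TopicVector,
                              noun_vec: TopicVector) -> TopicVector:
    """Element-wise product of verb and noun topic vectors.

    Retains only topics preferred by both words.  Not renormalized; a
    product that is identically zero (disjoint topic supports) is flagged
    degenerate and rejected by downstream cosine distances.
    """
    if verb_vec.K != noun_vec.K:
        raise ValueError("verb and noun vectors have different K")
    prod = verb_vec.loadings * noun_vec.loadings
    degenerate = not (prod > 0).any()
    if degenerate:
        log.warning("verb-weighted vector for (%s, %s) is identically zero",
                    verb_vec.item_id, noun_vec.item_id)
    return TopicVector(prod, kind="verb_weighted",
                       item_id=f"{verb_vec.item_id}|{noun_vec.item_id}",
                       normalized=False, degenerate=degenerate)


def cosine_distance(a, b) -> float:
    """1 − cos(a, b); in [0, 1] for nonnegative vectors.

    Symmetric and invariant to positive rescaling of either argument.
    Zero (or degenerate-flagged) vectors are rejected.
    """
    for v in (a, b):
        if isinstance(v, TopicVector) and v.degenerate:
            raise DegenerateInputError(
                f"cosine distance on degenerate vector {v.item_id!r}")
    x = a.loadings if isinstance(a, TopicVector) else np.asarray(a, dtype=float)
    y = b.loadings if isinstance(b, TopicVector) else np.asarray(b, dtype=float)
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise DegenerateInputError("cosine distance of a zero vector is undefined")
    return float(1.0 - np.dot(x, y) / (nx * ny))


def constraint_error(verb_vec: TopicVector, noun_vec: TopicVector) -> float:
    """Verb constraint error: cosine distance between verb and noun vectors.

    Smaller values mean the noun fits the verb's semantic constraints more
    easily.
    """
    return cosine_distance(verb_vec, noun_vec)
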