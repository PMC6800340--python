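"""Representational dissimilarity matrices (RDMs) and rank-based model fit.

A model RDM is an N × N symmetric zero-diagonal matrix whose entry (i, j)
is the dissimilarity between sentences i and j under one semantic model.
Five model RDMs are built from a stimulus set and a fitted topic model:

* ``verb_topic``           — cosine distance between verb topic vectors;
* ``verb_topic_entropy``   — |ΔH| of verb topic entropies;
* ``noun_topic``           — cosine distance between noun topic vectors;
* ``verb_weighted_noun``   — cosine distance between verb-weighted noun
                             vectors (element-wise verb × noun products);
* ``verb_constraint_error``— |Δ| of verb-constraint-error scalars.

A sixth, the verb–noun *interaction*, is not a matrix of its own: it is the
verb-weighted noun RDM fitted with the verb and noun topic RDMs partialled
out at correlation time (see :func:`partial_spearman`).

RDMs are compared through their condensed upper-triangle vectors in a fixed
row-major order shared by all RDMs over the same item order.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
from scipy.linalg import orth
from scipy.stats import rankdata

from . import topics as T

__all__ = [
    "StimulusSet",
    "RDM",
    "UndefinedCorrelationError",
    "distance_rdm",
    "difference_rdm",
    "vectorize_upper",
    "condensed_to_matrix",
    "partial_spearman",
    "build_model_rdms",
    "MODEL_LABELS",
]

MODEL_LABELS = ("verb_topic", "verb_topic_entropy", "noun_topic",
                "verb_weighted_noun", "verb_constraint_error")

_SYM_TOL = 1e-10


class UndefinedCorrelationError(ValueError):
    """A correlation is requested on a constant (zero-variance) vector."""


@dataclass
class StimulusSet:
    """Ordered sentence design: (sentence_id, set_id, verb_id, noun_id) rows.

    Within a set there are exactly ``verbs_per_set`` distinct verbs, each
    paired with ``nouns_per_verb`` distinct nouns.  The row order is the
    canonical RDM row order.
    """

    items: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sentence_id", "set_id", "verb_id", "noun_id"}
        if not required.issubset(self.items.columns):
            raise ValueError(f"stimulus table needs columns {sorted(required)}")
        if self.items["sentence_id"].duplicated().any():
            raise ValueError("duplicate sentence ids")
        counts = self.items.groupby("set_id")["verb_id"].nunique()
        if counts.nunique() != 1:
            raise ValueError("sets differ in number of distinct verbs")
        per_verb = self.items.groupby(["set_id", "verb_id"])["noun_id"].nunique()
        if per_verb.nunique() != 1:
            raise ValueError("verbs differ in number of distinct nouns")
        pair_sizes = self.items.groupby(["set_id", "verb_id"]).size()
        if not (pair_sizes == per_verb).all():
            raise ValueError("repeated (verb, noun) pairing within a set")

    @property
    def n_sets(self) -> int:
        return self.items["set_id"].nunique()

    @property
    def verbs_per_set(self) -> int:
        return int(self.items.groupby("set_id")["verb_id"].nunique().iloc[0])

    @property
    def nouns_per_verb(self) -> int:
        return int(self.items.groupby(["set_id", "verb_id"])["noun_id"]
                   .nunique().iloc[0])

    @property
    def sentence_ids(self) -> list[str]:
        return [str(s) for s in self.items["sentence_id"]]

    def __len__(self) -> int:
        return len(self.items)

    @classmethod
    def from_tsv(cls, path) -> "StimulusSet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(df)

    def to_tsv(self, path) -> None:
        self.items.to_csv(path, sep="\t", index=False)


@dataclass
class RDM:
    """N × N symmetric zero-diagonal dissimilarity matrix with item labels."""

    values: np.ndarray
    item_order: list[str]
    label: str
    construction: str  # cosine | abs_difference | correlation_distance

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.item_order)
        if self.values.shape != (n, n):
            raise ValueError("RDM shape does not match item order")
        if np.abs(self.values - self.values.T).max() > _SYM_TOL:
            raise ValueError("RDM is not symmetric")
        if np.abs(np.diag(self.values)).max() > _SYM_TOL:
            raise ValueError("RDM diagonal is not zero")

    @property
    def n(self) -> int:
        return len(self.item_order)

    def condensed(self) -> np.ndarray:
        return vectorize_upper(self)

    def reindex(self, item_order: list[str]) -> "RDM":
        """Restrict/reorder to a subset of items (e.g. retained trials)."""
        pos = {s: i for i, s in enumerate(self.item_order)}
        missing = [s for s in item_order if s not in pos]
        if missing:
            raise ValueError(f"items not in RDM: {missing[:5]}")
        idx = np.array([pos[s] for s in item_order])
        return RDM(self.values[np.ix_(idx, idx)], list(item_order),
                   self.label, self.construction)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("rdm", data=self.values)
            f.create_dataset("item_order",
                             data=np.array(self.item_order, dtype=object),
                             dtype=h5py.string_dtype())
            d.attrs["label"] = self.label
            d.attrs["construction"] = self.construction

    @classmethod
    def load(cls, path) -> "RDM":
        with h5py.File(path, "r") as f:
            items = [s.decode() if isinstance(s, bytes) else str(s)
                     for s in f["item_order"][()]]
            d = f["rdm"]
            return cls(d[()], items, str(d.attrs["label"]),
                       str(d.attrs["construction"]))


def vectorize_upper(rdm: RDM | np.ndarray) -> np.ndarray:
    """Row-major upper-triangle condensed vector (length N(N−1)/2)."""
    m = rdm.values if isinstance(rdm, RDM) else np.asarray(rdm)
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu].copy()

def condensed_to_matrix(vec: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`."""
    vec = np.asarray(vec, dtype=float)
    if vec.size != n * (n - 1) // 2:
        raise ValueError("condensed length inconsistent with n")
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = vec
    m += m.T
    return m


def distance_rdm(vectors, item_order: list[str], label: str) -> RDM:
    """Pairwise cosine-distance RDM over per-sentence loading vectors.

    Items with byte-identical loading vectors (e.g. two sentences sharing a
    verb) get an exact zero entry.
    """
    arrs = []
    for sid, v in zip(item_order, vectors):
        if isinstance(v, T.TopicVector):
            if v.degenerate:
                raise T.DegenerateInputError(
                    f"degenerate vector for sentence {sid!r}")
            arrs.append(v.loadings)
        else:
            arrs.append(np.asarray(v, dtype=float))
    X = np.stack(arrs)
    norms = np.linalg.norm(X, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise T.DegenerateInputError(
            f"zero vector for sentence {item_order[bad[0]]!r}")
    Z = X / norms[:, None]
    D = 1.0 - Z @ Z.T
    np.clip(D, 0.0, None, out=D)
    # exact zeros for identical vectors
    groups: dict[bytes, list[int]] = {}
    for i, row in enumerate(X):
        groups.setdefault(row.tobytes(), []).append(i)
    for idx in groups.values():
        if len(idx) > 1:
            D[np.ix_(idx, idx)] = 0.0
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return RDM(D, list(item_order), label, "cosine")


def difference_rdm(scalars, item_order: list[str], label: str) -> RDM:
    """Absolute-difference RDM over per-sentence scalar values."""
    s = np.asarray(list(scalars), dtype=float)
    if not np.all(np.isfinite(s)):
        bad = int(np.flatnonzero(~np.isfinite(s))[0])
        raise ValueError(f"non-finite scalar for sentence {item_order[bad]!r}")
    D = np.abs(s[:, None] - s[None, :])
    return RDM(D, list(item_order), label, "abs_difference")


def partial_spearman(target, reference, controls=()) -> float:
    """Spearman correlation of target and reference, partialling out controls.

    Every vector is rank-transformed (average ranks for ties); the ranks of
    target and reference are each residualized against an intercept plus
    the rank-transformed controls, and the Pearson correlation of the two
    residual vectors is returned.  With no controls this is the ordinary
    Spearman correlation.

    Convention: if either residual vector is numerically zero (the vector
    is fully explained by the controls), the partial correlation is 0.
    """
    t = np.asarray(target, dtype=float)
    r = np.asarray(reference, dtype=float)
    ctrl = [np.asarray(c, dtype=float) for c in controls]
    n = t.size
    if r.size != n or any(c.size != n for c in ctrl):
        raise ValueError("all vectors must have equal length")
    if n < 3 + len(ctrl):
        raise ValueError("too few observations for partial correlation")
    tr = rankdata(t)
    rr = rankdata(r)
    if np.ptp(tr) == 0 or np.ptp(rr) == 0:
        raise UndefinedCorrelationError("constant vector after ranking")
    X = np.column_stack([np.ones(n)] + [rankdata(c) for c in ctrl])
    Q = orth(X)
    t_res = tr - Q @ (Q.T @ tr)
    r_res = rr - Q @ (Q.T @ rr)
    nt, nr = np.linalg.norm(t_res), np.linalg.norm(r_res)
    scale = np.linalg.norm(tr) * np.linalg.norm(rr)
    if nt * nr <= 1e-12 * max(scale, 1.0):
        return 0.0
    return float(t_res @ r_res / (nt * nr))


def build_model_rdms(model: "T.TopicModel", stimuli: StimulusSet,
                     weighting: bool = True) -> dict[str, RDM]:
    """Build the five model RDMs for a stimulus set from a fitted topic model.

    When ``weighting`` is on, per-topic informativeness weights are applied
    to both verb and noun topic vectors before any downstream quantity
    (entropy, product, cosine distance) is computed.
    """
    order = stimuli.sentence_ids
    w = model.informativeness if weighting else None

    verb_vecs, noun_vecs, vw_vecs, entropies, errors = [], [], [], [], []
    for _, row in stimuli.items.iterrows():
        vv = T.verb_topic_vector(model, str(row["verb_id"]))
        nv = T.noun_topic_vector(model, str(row["noun_id"]))
        if w is not None:
            vv = T.apply_informativeness(vv, w)
            nv = T.apply_informativeness(nv, w)
        verb_vecs.append(vv)
        noun_vecs.append(nv)
        vw_vecs.append(T.verb_weighted_noun_vector(vv, nv))
        entropies.append(T.topic_entropy(vv))
        errors.append(T.constraint_error(vv, nv))

    return {
        "verb_topic": distance_rdm(verb_vecs, order, "verb_topic"),
        "verb_topic_entropy": difference_rdm(entropies, order,
                                             "verb_topic_entropy"),
        "noun_topic": distance_rdm(noun_vecs, order, "noun_topic"),
        "verb_weighted_noun": distance_rdm(vw_vecs, order, "verb_weighted_noun"),
        "verb_constraint_error": difference_rdm(errors, order,
                                                "verb_constraint_error"),
    }
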