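"""Synthetic inputs with planted ground truth.

Everything the pipeline consumes can be generated here with known
structure, replacing a corpus and source-localized recordings:

* a planted topic model (Dirichlet topic-word rows) and a co-occurrence
  table sampled from it, for parameter-recovery tests of the LDA fit;
* a stimulus design (sets of sentences, three verbs per set, two nouns per
  verb) mirroring the 60-set × 6-sentence layout;
* source-space epochs on an abstract quasi-uniform 3-D point-cloud mesh:
  spatially and temporally smoothed Gaussian noise, plus planted effects —
  per-item patterns inside a chosen region and time window whose
  correlation-distance geometry matches a target model RDM;
* directed coupling between two regions: the target region's patterns
  receive a fixed linear map of the source region's patterns from
  ``delay_ms`` earlier.

Planted patterns are built by factorizing the similarity matrix 1 − D of
the target RDM (eigendecomposition, top nonnegative components) and
mapping the item coordinates through a random orthonormal basis of patch
space that is orthogonal to the constant vector.  Noiseless patches then
reproduce the target RDM's correlation distances exactly up to the
positive-semidefinite truncation error.

All generators are deterministic given their seed.  The mesh is seed-
independent (a Halton sequence), so planted structure *location* is stable
across seeds while noise varies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.spatial import cKDTree
from scipy.stats import qmc

from .rdm import RDM, StimulusSet
from .ssrsa import SourceEpochs
from .topics import CooccurrenceTable, TopicModel, topic_informativeness

__all__ = [
    "MeshSpec",
    "PlantedEffect",
    "GroundTruth",
    "generate_topic_ground_truth",
    "generate_cooccurrence",
    "generate_stimulus_set",
    "make_mesh",
    "embed_rdm_patterns",
    "generate_source_epochs",
    "plant_directed_connectivity",
]


# ---------------------------------------------------------------------------
# Topic-side generators


def generate_topic_ground_truth(K: int, V: int, concentration: float,
                                seed: int = 0) -> TopicModel:
    """A planted topic model: K topic-word rows ~ Dirichlet(concentration).

    Small concentrations give well-separated, sparse topics; large
    concentrations approach the uniform distribution.  The topic prior is
    uniform.
    """
    if K < 1 or V < K:
        raise ValueError("need K >= 1 and V >= K")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    rows = rng.dirichlet(np.full(V, concentration), size=K)
    rows = rows / rows.sum(axis=1, keepdims=True)
    vocab = [f"noun{i:04d}" for i in range(V)]
    model = TopicModel(K=K, topic_word=rows, topic_prior=np.full(K, 1.0 / K),
                       vocabulary=vocab, informativeness=np.ones(K),
                       fit_meta={"synthetic": True, "seed": seed,
                                 "concentration": concentration})
    model.informativeness = topic_informativeness(model)
    return model


def generate_cooccurrence(truth: TopicModel, n_verbs: int,
                          tokens_per_verb: int, verb_concentration: float,
                          seed: int = 0,
                          ) -> tuple[CooccurrenceTable, np.ndarray]:
    """Sample a verb × noun count table from a planted topic model.

    Per verb: draw a topic mixture from a symmetric
    Dirichlet(verb_concentration), then draw ``tokens_per_verb`` noun
    tokens by topic-then-word sampling.  Returns the integer count table
    and the planted per-verb topic mixtures (n_verbs × K); the mixtures
    are also registered as ``truth.doc_topic`` entries so the planted
    model can serve verb topic vectors directly.
    """
    if n_verbs < 1 or tokens_per_verb < 1:
        raise ValueError("n_verbs and tokens_per_verb must be positive")
    if verb_concentration <= 0:
        raise ValueError("verb_concentration must be positive")
    rng = np.random.default_rng(seed)
    K, V = truth.topic_word.shape
    thetas = rng.dirichlet(np.full(K, verb_concentration), size=n_verbs)
    rows = []
    for i in range(n_verbs):
        verb = f"verb{i:04d}"
        topic_counts = rng.multinomial(tokens_per_verb, thetas[i])
        noun_counts = np.zeros(V, dtype=int)
        for k in np.flatnonzero(topic_counts):
            noun_counts += rng.multinomial(topic_counts[k], truth.topic_word[k])
        for j in np.flatnonzero(noun_counts):
            rows.append((verb, truth.vocabulary[j], float(noun_counts[j])))
        truth.doc_topic[verb] = thetas[i]
    table = pd.DataFrame(rows, columns=["verb", "noun", "weight"])
    return CooccurrenceTable(table), thetas


def generate_stimulus_set(n_sets: int = 60, verbs_per_set: int = 3,
                          nouns_per_verb: int = 2, seed: int = 0,
                          verbs: list[str] | None = None,
                          nouns: list[str] | None = None) -> StimulusSet:
    """A sentence design: per set, ``verbs_per_set`` distinct verbs each
    paired with ``nouns_per_verb`` distinct nouns.

    Defaults give the canonical 60 × 3 × 2 = 360-sentence layout.  Verb and
    noun pools default to synthetic tokens; pools are sampled without
    replacement within a set (and globally when large enough).
    """
    if min(n_sets, verbs_per_set, nouns_per_verb) < 1:
        raise ValueError("design counts must be positive")
    rng = np.random.default_rng(seed)
    need_v, need_n = verbs_per_set, verbs_per_set * nouns_per_verb
    if verbs is None:
        verbs = [f"verb{i:04d}" for i in range(n_sets * need_v)]
    if nouns is None:
        nouns = [f"noun{i:04d}" for i in range(n_sets * need_n)]
    if len(verbs) < need_v or len(set(verbs)) < need_v:
        raise ValueError("not enough distinct verbs for one set")
    if len(nouns) < need_n or len(set(nouns)) < need_n:
        raise ValueError("not enough distinct nouns for one set")
    global_v = len(verbs) >= n_sets * need_v
    global_n = len(nouns) >= n_sets * need_n
    v_pool = rng.permutation(np.array(verbs, dtype=object))
    n_pool = rng.permutation(np.array(nouns, dtype=object))
    rows = []
    sid = 0
    for s in range(n_sets):
        vs = (v_pool[s * need_v:(s + 1) * need_v] if global_v
              else rng.choice(v_pool, size=need_v, replace=False))
        ns = (n_pool[s * need_n:(s + 1) * need_n] if global_n
              else rng.choice(n_pool, size=need_n, replace=False))
        for vi, verb in enumerate(vs):
            for ni in range(nouns_per_verb):
                noun = ns[vi * nouns_per_verb + ni]
                rows.append((f"s{sid:04d}", f"set{s:03d}", str(verb), str(noun)))
                sid += 1
    return StimulusSet(pd.DataFrame(
        rows, columns=["sentence_id", "set_id", "verb_id", "noun_id"]))


# ---------------------------------------------------------------------------
# Source-space generators


@dataclass
class MeshSpec:
    """Abstract source mesh: a quasi-uniform point cloud in a cube."""

    n_vertices: int = 500
    scale_mm: float = 60.0


@dataclass
class PlantedEffect:
    """A model-RDM geometry planted in a vertex region and time window."""

    rdm: RDM
    vertices: np.ndarray
    window_ms: tuple[float, float]
    snr: float

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=int)


@dataclass
class GroundTruth:
    """Record of everything planted, reproducible from the master seed."""

    seed: int
    mesh: dict = field(default_factory=dict)
    effects: list[dict] = field(default_factory=list)
    coupling: dict | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=2, default=_jsonable)


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer, np.floating)):
        return x.item()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def make_mesh(spec: MeshSpec) -> np.ndarray:
    """Deterministic quasi-uniform 3-D point cloud (Halton sequence)."""
    h = qmc.Halton(d=3, scramble=False)
    h.fast_forward(1)  # skip the origin
    return spec.scale_mm * h.random(spec.n_vertices)


def embed_rdm_patterns(rdm_values: np.ndarray, n_features: int,
                       rng: np.random.Generator,
                       max_dim: int | None = None) -> np.ndarray:
    """Per-item pattern vectors whose correlation distances realize an RDM.

    Factorizes the similarity matrix G = 1 − D into item coordinates and
    maps them through a random orthonormal basis of feature space
    orthogonal to the constant vector; feature-mean-zero patterns make
    Pearson correlation equal to cosine similarity.  When G is not
    positive semidefinite its diagonal is shifted up just enough (G + αI),
    which rescales all pairwise correlations by 1/(1 + α): the realized
    correlation distances are then an exact strictly monotone transform of
    D, so rank-based model fits see the planted geometry exactly.  For
    cosine-built RDMs (G already a Gram matrix) the reproduction is exact
    without any shift.
    """
    D = np.asarray(rdm_values, dtype=float)
    n = D.shape[0]
    G = 1.0 - D
    G = (G + G.T) / 2.0
    evals, evecs = np.linalg.eigh(G)
    tol = 1e-10 * max(evals.max(), 1.0)
    if evals.min() < tol:
        shift = tol - evals.min()
        G = G + shift * np.eye(n)
        evals = evals + shift
    pos = evals > tol / 2
    d = int(pos.sum())
    if max_dim is not None:
        d = min(d, max_dim)
    if d >= n_features:
        raise ValueError(
            f"embedding dimension {d} exceeds the region/window patch "
            f"size ({n_features} features)")
    top = np.argsort(evals)[::-1][:d]
    Z = evecs[:, top] * np.sqrt(evals[top])
    B = rng.standard_normal((n_features, d))
    ones = np.ones(n_features) / np.sqrt(n_features)
    B -= ones[:, None] * (ones @ B)
    Q, _ = np.linalg.qr(B)
    return Z @ Q.T


def generate_source_epochs(stimuli: StimulusSet,
                           mesh_spec: MeshSpec | None = None,
                           planted_effects: list[PlantedEffect] | tuple = (),
                           n_subjects: int = 12,
                           n_samples: int = 300,
                           step_ms: float = 2.0,
                           noise_temporal_sigma_ms: float = 4.0,
                           noise_spatial_sigma_mm: float = 5.0,
                           seed: int = 0,
                           ) -> tuple[list[SourceEpochs], GroundTruth]:
    """Per-subject source-space epochs with planted representational geometry.

    Baseline activity is unit-variance Gaussian noise, smoothed along time
    (Gaussian kernel, ``noise_temporal_sigma_ms``) and across the mesh
    (Gaussian spatial kernel truncated at 2 sigma).  Within each planted
    effect's region × window, per-item patterns embedding the target RDM
    are added, scaled so their feature RMS equals ``snr`` times the noise
    standard deviation.  Noise is independent per subject.  The planted
    *geometry* (region, window, and the RDM the patterns realize) is
    shared across subjects, but each subject receives an independent
    random pattern realization of it — mirroring real recordings, where
    representational geometry, not the voxel-level pattern, is what
    subjects have in common.
    """
    mesh_spec = mesh_spec or MeshSpec()
    coords = make_mesh(mesh_spec)
    nv = mesh_spec.n_vertices
    times = step_ms * np.arange(n_samples)
    n_items = len(stimuli)
    ids = stimuli.sentence_ids

    ss = np.random.SeedSequence(seed)
    effect_ss, *subject_ss = ss.spawn(1 + n_subjects)

    # planted geometry, validated once; per-subject realizations below
    effects = []
    truth = GroundTruth(seed=seed,
                        mesh={"n_vertices": nv, "scale_mm": mesh_spec.scale_mm})
    for eff in planted_effects:
        lo = int(round(eff.window_ms[0] / step_ms))
        hi = int(round(eff.window_ms[1] / step_ms))
        if lo < 0 or hi > n_samples or lo >= hi:
            raise ValueError("planted window outside the epoch")
        if eff.vertices.min() < 0 or eff.vertices.max() >= nv:
            raise ValueError("planted region outside the mesh")
        m, w = eff.vertices.size, hi - lo
        D = eff.rdm.reindex(ids).values
        effects.append((eff, lo, hi, D, m, w))
        truth.effects.append({"label": eff.rdm.label,
                              "vertices": eff.vertices,
                              "window_ms": list(eff.window_ms),
                              "snr": eff.snr})

    # spatial smoothing kernel (truncated, rows scaled to unit L2 norm)
    tree = cKDTree(coords)
    Ksp = tree.sparse_distance_matrix(
        tree, max_distance=2.0 * noise_spatial_sigma_mm,
        output_type="coo_matrix").tocsr()
    Ksp.data = np.exp(-Ksp.data ** 2 / (2.0 * noise_spatial_sigma_mm ** 2))
    Ksp.setdiag(1.0)
    row_norm = np.sqrt(np.asarray(Ksp.multiply(Ksp).sum(axis=1)).ravel())
    Ksp = Ksp.multiply(1.0 / row_norm[:, None]).tocsr()

    sigma_samples = noise_temporal_sigma_ms / step_ms
    epochs = []
    for s, sub_ss in enumerate(subject_ss):
        rng = np.random.default_rng(sub_ss)
        noise = rng.standard_normal((n_items, nv, n_samples))
        noise = gaussian_filter1d(noise, sigma=sigma_samples, axis=2)
        noise = (Ksp @ noise.transpose(1, 0, 2).reshape(nv, -1)) \
            .reshape(nv, n_items, n_samples).transpose(1, 0, 2)
        noise /= noise.std()
        for eff, lo, hi, D, m, w in effects:
            P = embed_rdm_patterns(D, m * w, rng)
            P *= eff.snr / np.sqrt(np.mean(P ** 2))
            noise[:, eff.vertices, lo:hi] += P.reshape(n_items, m, w)
        epochs.append(SourceEpochs(noise.astype(np.float32), coords, times,
                                   list(ids), subject_id=f"sub{s:02d}"))
    return epochs, truth


def plant_directed_connectivity(epochs: list[SourceEpochs],
                                roi_a, roi_b, delay_ms: float,
                                gain: float, seed: int = 0,
                                ) -> tuple[list[SourceEpochs], GroundTruth]:
    """Add lagged A→B coupling: B(t) += gain · M · A(t − delay).

    The linear map M (target vertices × source vertices, scaled to preserve
    unit variance) is fixed per subject and seeded.  ROIs must be disjoint;
    the delay must be a positive multiple of the sampling step.
    """
    va = np.asarray(getattr(roi_a, "vertices", roi_a), dtype=int)
    vb = np.asarray(getattr(roi_b, "vertices", roi_b), dtype=int)
    if np.intersect1d(va, vb).size:
        raise ValueError("source and target ROIs overlap")
    step = epochs[0].step_ms
    d = delay_ms / step
    if delay_ms <= 0 or abs(d - round(d)) > 1e-9:
        raise ValueError("delay must be a positive multiple of the sampling step")
    d = int(round(d))
    ss = np.random.SeedSequence(seed)
    out = []
    for ep, sub_ss in zip(epochs, ss.spawn(len(epochs))):
        rng = np.random.default_rng(sub_ss)
        M = rng.standard_normal((vb.size, va.size)) / np.sqrt(va.size)
        data = np.asarray(ep.data, dtype=float).copy()
        if gain != 0.0:
            src = data[:, va, :-d] if d > 0 else data[:, va, :]
            data[:, vb, d:] += gain * np.einsum("bm,nmt->nbt", M, src)
        out.append(SourceEpochs(data.astype(ep.data.dtype),
                                ep.vertex_coords.copy(), ep.times_ms.copy(),
                                list(ep.trial_ids), ep.subject_id))
    truth = GroundTruth(seed=seed,
                        coupling={"source": va, "target": vb,
                                  "delay_ms": float(delay_ms),
                                  "gain": float(gain)})
    return out, truth
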