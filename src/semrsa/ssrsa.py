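"""Spatiotemporal searchlight RSA on source-space epochs.

The data side of RSA: within a searchlight (all vertices within a spatial
radius of a centre vertex, crossed with a sliding time window), each
trial's vertices × samples patch is flattened to a feature vector and the
pairwise Pearson correlation distance (1 − r) between trials forms the
*data RDM*.  The data RDM is compared to a model RDM by Spearman rank
correlation (optionally partialling out control model RDMs), giving a
model-fit time course per vertex.  Group inference uses one-tailed
one-sample t tests across subjects with cluster-mass permutation
correction based on random per-subject sign flips.

Multivariate noise normalization (spatial whitening by an inverse square
root of a shrunk noise covariance) can be applied to epochs beforehand to
improve the reliability of the correlation distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import h5py
import numpy as np
import scipy.sparse as sp
from scipy.linalg import orth
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.stats import rankdata, t as student_t

from .rdm import RDM, UndefinedCorrelationError, vectorize_upper

__all__ = [
    "SourceEpochs",
    "SearchlightSpec",
    "FitMap",
    "Cluster",
    "GroupResult",
    "multivariate_normalize",
    "searchlight_neighborhoods",
    "spatial_adjacency",
    "data_rdm",
    "model_fit_map",
    "group_cluster_inference",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Containers


@dataclass
class SourceEpochs:
    """Source-space epochs: trials × vertices × samples with geometry.

    ``times_ms`` must be uniformly spaced; ``trial_ids`` align trials with
    a stimulus set's sentence order (missing trials are allowed).
    """

    data: np.ndarray
    vertex_coords: np.ndarray
    times_ms: np.ndarray
    trial_ids: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.vertex_coords = np.asarray(self.vertex_coords, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        n, v, t = self.data.shape
        if self.vertex_coords.shape != (v, 3):
            raise ValueError("vertex_coords must be (n_vertices, 3)")
        if not np.all(np.isfinite(self.vertex_coords)):
            raise ValueError("vertex coordinates must be finite")
        if self.times_ms.size != t:
            raise ValueError("times_ms length must match samples")
        if len(self.trial_ids) != n:
            raise ValueError("trial_ids length must match trials")
        steps = np.diff(self.times_ms)
        if steps.size and np.abs(steps - steps[0]).max() > 1e-6:
            raise ValueError("time axis must be uniformly sampled")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def step_ms(self) -> float:
        return float(self.times_ms[1] - self.times_ms[0])

    def time_index(self, time_ms: float) -> int:
        idx = int(round((time_ms - self.times_ms[0]) / self.step_ms))
        if not (0 <= idx < self.n_samples) or \
                abs(self.times_ms[idx] - time_ms) > 1e-6:
            raise ValueError(f"{time_ms} ms is not on the epoch time axis")
        return idx

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            g = f.create_group("epochs")
            g.create_dataset("data", data=self.data.astype(np.float32))
            g.create_dataset("coords", data=self.vertex_coords)
            g.create_dataset("times_ms", data=self.times_ms)
            g.create_dataset("trial_ids",
                             data=np.array(self.trial_ids, dtype=object),
                             dtype=h5py.string_dtype())
            g.attrs["subject_id"] = self.subject_id

    @classmethod
    def load(cls, path) -> "SourceEpochs":
        with h5py.File(path, "r") as f:
            g = f["epochs"]
            trial_ids = [s.decode() if isinstance(s, bytes) else str(s)
                         for s in g["trial_ids"][()]]
            return cls(g["data"][()], g["coords"][()], g["times_ms"][()],
                       trial_ids, str(g.attrs.get("subject_id", "")))


@dataclass
class SearchlightSpec:
    """Searchlight geometry: spatial radius (mm), temporal radius (ms).

    ``mask`` restricts both searchlight centres and members to a vertex
    subset (indices); ``center_step`` strides the centre-time grid in
    samples (1 = every sample).
    """

    spatial_radius_mm: float = 10.0
    temporal_radius_ms: float = 30.0
    mask: np.ndarray | None = None
    center_step: int = 1

    def __post_init__(self) -> None:
        if self.spatial_radius_mm < 0 or self.temporal_radius_ms < 0:
            raise ValueError("searchlight radii must be >= 0")
        if self.center_step < 1:
            raise ValueError("center_step must be >= 1")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=int)
            if self.mask.size == 0:
                raise ValueError("searchlight mask is empty")


@dataclass
class FitMap:
    """Per-subject model fit: Spearman rho over (vertex, centre time).

    ``rho`` is (n_mask_vertices, n_centres); NaN marks centres whose full
    window does not fit in the epoch.
    """

    rho: np.ndarray
    vertices: np.ndarray        # original vertex indices of rows
    center_times_ms: np.ndarray
    model_label: str
    subject_id: str = ""


@dataclass
class Cluster:
    points: np.ndarray  # flat indices into the (vertex, time) grid
    mass: float
    p: float


@dataclass
class GroupResult:
    """Group-level t map with cluster-permutation significance."""

    t_map: np.ndarray           # (n_vertices_in_map, n_centres), NaN = undefined
    mask: np.ndarray            # bool, same shape: significant points
    clusters: list[Cluster]
    vertices: np.ndarray
    center_times_ms: np.ndarray
    model_label: str
    point_alpha: float
    cluster_alpha: float
    n_perm: int
    seed: int

    def cluster_table(self):
        import pandas as pd
        rows = [{"cluster": i, "n_points": len(c.points),
                 "mass": c.mass, "p": c.p}
                for i, c in enumerate(self.clusters)]
        return pd.DataFrame(rows, columns=["cluster", "n_points", "mass", "p"])

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("t_map", data=self.t_map)
            f.create_dataset("mask", data=self.mask.astype(np.uint8))
            f.create_dataset("vertices", data=self.vertices)
            f.create_dataset("center_times_ms", data=self.center_times_ms)
            g = f.create_group("clusters")
            for i, c in enumerate(self.clusters):
                cg = g.create_group(str(i))
                cg.create_dataset("points", data=c.points)
                cg.attrs["mass"] = c.mass
                cg.attrs["p"] = c.p
            f.attrs.update({"model_label": self.model_label,
                            "point_alpha": self.point_alpha,
                            "cluster_alpha": self.cluster_alpha,
                            "n_perm": self.n_perm, "seed": self.seed})

    @classmethod
    def load(cls, path) -> "GroupResult":
        with h5py.File(path, "r") as f:
            clusters = []
            for key in sorted(f["clusters"], key=int):
                cg = f["clusters"][key]
                clusters.append(Cluster(cg["points"][()],
                                        float(cg.attrs["mass"]),
                                        float(cg.attrs["p"])))
            return cls(f["t_map"][()], f["mask"][()].astype(bool), clusters,
                       f["vertices"][()], f["center_times_ms"][()],
                       str(f.attrs["model_label"]),
                       float(f.attrs["point_alpha"]),
                       float(f.attrs["cluster_alpha"]),
                       int(f.attrs["n_perm"]), int(f.attrs["seed"]))


# ---------------------------------------------------------------------------
# Multivariate noise normalization


def multivariate_normalize(epochs: SourceEpochs,
                           shrinkage: float | str = "auto") -> SourceEpochs:
    """Spatially whiten epochs by the inverse square root of noise covariance.

    The vertices × vertices noise covariance is estimated from
    trial-demeaned data pooled over all samples, shrunk toward its diagonal
    by a factor ``shrinkage`` (a Ledoit–Wolf-style estimate when "auto"),
    and each trial's spatial pattern at each sample is multiplied by the
    inverse matrix square root.
    """
    if epochs.n_trials < 2:
        raise ValueError("noise normalization needs at least 2 trials")
    data = np.asarray(epochs.data, dtype=float)
    resid = data - data.mean(axis=0, keepdims=True)
    pooled = resid.transpose(0, 2, 1).reshape(-1, epochs.n_vertices)
    cov = pooled.T @ pooled / pooled.shape[0]

    if shrinkage == "auto":
        from sklearn.covariance import ledoit_wolf
        _, lam = ledoit_wolf(pooled, assume_centered=True)
    else:
        lam = float(shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("shrinkage must lie in [0, 1]")
    shrunk = (1.0 - lam) * cov + lam * np.diag(np.diag(cov))

    evals, evecs = np.linalg.eigh(shrunk)
    if evals.min() <= 1e-12 * max(evals.max(), 1.0):
        raise np.linalg.LinAlgError(
            "noise covariance is singular; increase shrinkage (e.g. 'auto')")
    W = (evecs / np.sqrt(evals)) @ evecs.T
    out = np.einsum("uv,nvt->nut", W, data)
    return SourceEpochs(out, epochs.vertex_coords.copy(),
                        epochs.times_ms.copy(), list(epochs.trial_ids),
                        epochs.subject_id)


# ---------------------------------------------------------------------------
# Searchlight geometry


def searchlight_neighborhoods(coords: np.ndarray,
                              spec: SearchlightSpec) -> list[np.ndarray]:
    """Per-vertex neighborhoods: all vertices within the spatial radius.

    Each vertex is always a member of its own neighborhood.
    """
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    tree = cKDTree(coords)
    hoods = tree.query_ball_point(coords, r=spec.spatial_radius_mm)
    return [np.array(sorted(h), dtype=int) for h in hoods]


def spatial_adjacency(coords: np.ndarray, radius_mm: float) -> sp.csr_matrix:
    """Sparse vertex graph: an edge iff Euclidean distance <= radius (no loops)."""
    coords = np.asarray(coords, dtype=float)
    tree = cKDTree(coords)
    A = tree.sparse_distance_matrix(tree, max_distance=radius_mm,
                                    output_type="coo_matrix")
    keep = A.row != A.col
    n = coords.shape[0]
    return sp.csr_matrix((np.ones(keep.sum(), dtype=bool),
                          (A.row[keep], A.col[keep])), shape=(n, n))


def _lattice_band(n: int) -> sp.csr_matrix:
    """±1-neighbor band matrix for a 1-D lattice."""
    if n == 1:
        return sp.csr_matrix((1, 1), dtype=bool)
    d = np.ones(n - 1, dtype=bool)
    return sp.diags([d, d], offsets=[-1, 1], format="csr", dtype=bool)


def spatiotemporal_adjacency(space: sp.spmatrix, n_time: int) -> sp.csr_matrix:
    """Adjacency over the flattened (vertex, time) grid (index = v*T + t).

    Two points are adjacent if they share a time and are spatial neighbors,
    or share a vertex and are consecutive in time.
    """
    nv = space.shape[0]
    return (sp.kron(space, sp.eye(n_time, dtype=bool, format="csr"),
                    format="csr")
            + sp.kron(sp.eye(nv, dtype=bool, format="csr"),
                      _lattice_band(n_time), format="csr")).astype(bool)


def lattice_adjacency(shape: tuple[int, int]) -> sp.csr_matrix:
    """4-neighborhood adjacency on a 2-D lattice, flattened row-major."""
    n0, n1 = shape
    return (sp.kron(_lattice_band(n0), sp.eye(n1, dtype=bool, format="csr"),
                    format="csr")
            + sp.kron(sp.eye(n0, dtype=bool, format="csr"), _lattice_band(n1),
                      format="csr")).astype(bool)


# ---------------------------------------------------------------------------
# Data RDMs


def data_rdm(epochs: SourceEpochs, vertices, center_time_ms: float,
             temporal_radius_ms: float) -> RDM:
    """Correlation-distance data RDM for one searchlight patch.

    Each trial's (vertices × window samples) patch is flattened and the
    entry (i, j) is 1 − Pearson r between trials i and j.
    """
    vertices = np.asarray(vertices, dtype=int)
    c = epochs.time_index(center_time_ms)
    r = int(round(temporal_radius_ms / epochs.step_ms))
    lo, hi = c - r, c + r + 1
    if lo < 0 or hi > epochs.n_samples:
        raise ValueError("searchlight window exceeds the epoch")
    patch = np.asarray(epochs.data[:, vertices, lo:hi], dtype=float)
    feats = patch.reshape(epochs.n_trials, -1)
    if feats.shape[1] < 2:
        raise ValueError("searchlight patch needs >= 2 features")
    sd = feats.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise UndefinedCorrelationError(
            f"constant feature vector for trial {epochs.trial_ids[bad[0]]!r}")
    D = 1.0 - np.corrcoef(feats)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return RDM(D, list(epochs.trial_ids), "data", "correlation_distance")


# ---------------------------------------------------------------------------
# Model fit


def _rank_rows(x: np.ndarray) -> np.ndarray:
    """Row-wise average ranks (ties averaged), vectorized over rows.

    Equivalent to ``scipy.stats.rankdata(x, axis=1)``; implemented with a
    single argsort per row plus accumulate passes, which is faster on the
    wide row blocks the searchlight loop produces.  Sort stability is not
    required: members of a tie group all receive the same averaged rank.
    """
    L = x.shape[1]
    order = np.argsort(x, axis=1)
    sx = np.take_along_axis(x, order, axis=1)
    idx = np.arange(L)
    boundary = np.ones(x.shape, dtype=bool)
    boundary[:, 1:] = sx[:, 1:] != sx[:, :-1]
    start = np.maximum.accumulate(np.where(boundary, idx, 0), axis=1)
    rb = np.ones(x.shape, dtype=bool)
    rb[:, :-1] = boundary[:, 1:]
    end = np.minimum.accumulate(
        np.where(rb, idx, L - 1)[:, ::-1], axis=1)[:, ::-1]
    avg = (start + end) / 2.0 + 1.0
    ranks = np.empty_like(avg)
    np.put_along_axis(ranks, order, avg, axis=1)
    return ranks


def _residual_basis(condensed_controls: list[np.ndarray], length: int,
                    rank: bool = True) -> np.ndarray:
    """Orthonormal basis of span{intercept, (ranked) controls}."""
    cols = [np.ones(length)]
    cols += [rankdata(c) if rank else np.asarray(c, dtype=float)
             for c in condensed_controls]
    return orth(np.column_stack(cols))


def _align_model(model: RDM, trial_ids: list[str]) -> RDM:
    missing = [t for t in trial_ids if t not in set(model.item_order)]
    if missing:
        raise ValueError(f"trials without model entries: {missing[:5]}")
    return model.reindex(trial_ids)


def model_fit_map(epochs: SourceEpochs, model: RDM,
                  controls: list[RDM] | tuple = (),
                  spec: SearchlightSpec | None = None,
                  method: str = "spearman") -> FitMap:
    """Searchlight model fit across all vertices and centre times.

    For every masked vertex and every centre time whose full window lies in
    the epoch, the searchlight data RDM is correlated with the model RDM
    (rank-based partial Spearman by default; ``method='pearson'`` partials
    and correlates the raw condensed distances, which is the variant under
    which exactly additive structure is exactly partialled out).  Centres
    without a full window are NaN.

    The computation is vectorized: per centre time, batched window Gram
    matrices per vertex are aggregated over searchlight neighborhoods to
    obtain every searchlight's trial × trial correlation matrix at once.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    rank = method == "spearman"
    spec = spec or SearchlightSpec()
    n = epochs.n_trials
    if n < 3:
        raise ValueError("model fit needs at least 3 trials")
    m = _align_model(model, epochs.trial_ids)
    y = vectorize_upper(m)
    if rank:
        y = rankdata(y)
    if np.ptp(y) == 0:
        raise UndefinedCorrelationError("model RDM is constant")
    ctrl = [vectorize_upper(_align_model(c, epochs.trial_ids))
            for c in controls]
    Q = _residual_basis(ctrl, y.size, rank=rank)
    y_res = y - Q @ (Q.T @ y)
    ny = np.linalg.norm(y_res)
    self_partialled = ny <= 1e-12 * np.linalg.norm(y)

    mask = spec.mask if spec.mask is not None else np.arange(epochs.n_vertices)
    coords = epochs.vertex_coords[mask]
    hoods = searchlight_neighborhoods(coords, spec)
    sizes = np.array([h.size for h in hoods])
    nv = mask.size
    A = sp.csr_matrix(
        (np.ones(int(sizes.sum())),
         (np.repeat(np.arange(nv), sizes), np.concatenate(hoods))),
        shape=(nv, nv))

    r = int(round(spec.temporal_radius_ms / epochs.step_ms))
    T = epochs.n_samples
    centers = np.arange(0, T, spec.center_step)
    valid = (centers >= r) & (centers + r < T)
    rho = np.full((nv, centers.size), np.nan)
    if self_partialled:
        rho[:, valid] = 0.0
        return FitMap(rho, np.asarray(mask), epochs.times_ms[centers],
                      m.label, epochs.subject_id)

    X = np.ascontiguousarray(
        np.asarray(epochs.data, dtype=np.float64)[:, mask, :].transpose(1, 0, 2))
    iu = np.triu_indices(n, k=1)
    w = 2 * r + 1

    for ci in np.flatnonzero(valid):
        c = centers[ci]
        Wd = X[:, :, c - r:c + r + 1]
        G = Wd @ Wd.transpose(0, 2, 1)              # (nv, n, n)
        s1 = Wd.sum(axis=2)                          # (nv, n)
        s2 = np.einsum("vnt,vnt->vn", Wd, Wd)
        Su = A @ G[:, iu[0], iu[1]]                  # (nv, n_pairs)
        t1 = A @ s1
        t2 = A @ s2
        F = (w * sizes)[:, None].astype(float)
        mu = t1 / F
        var = t2 - F * mu ** 2
        if (var <= 1e-12 * np.maximum(t2, 1e-30)).any():
            vi, ti_ = np.argwhere(var <= 1e-12 * np.maximum(t2, 1e-30))[0]
            raise UndefinedCorrelationError(
                f"constant searchlight pattern for trial "
                f"{epochs.trial_ids[ti_]!r} at vertex {mask[vi]}")
        cov = Su - F * mu[:, iu[0]] * mu[:, iu[1]]
        d = 1.0 - cov / np.sqrt(var[:, iu[0]] * var[:, iu[1]])
        ranks = _rank_rows(d) if rank else d
        resid = ranks - (ranks @ Q) @ Q.T
        norms = np.linalg.norm(resid, axis=1)
        norms[norms == 0] = np.inf
        rho[:, ci] = (resid @ y_res) / (norms * ny)

    return FitMap(rho, np.asarray(mask), epochs.times_ms[centers],
                  m.label, epochs.subject_id)


# ---------------------------------------------------------------------------
# Group inference


def _t_values(mean: np.ndarray, sumsq: np.ndarray, n: int) -> np.ndarray:
    var = (sumsq - n * mean ** 2) / (n - 1)
    var = np.maximum(var, 1e-300)
    return mean / np.sqrt(var / n)


def cluster_sign_flip_test(stats: np.ndarray, adjacency: sp.spmatrix,
                           point_alpha: float, cluster_alpha: float,
                           n_perm: int, seed: int):
    """One-tailed sign-flip cluster-mass permutation test.

    ``stats`` is subjects × points (finite); ``adjacency`` a sparse graph
    over points.  Points with t above the one-tailed ``point_alpha``
    quantile (df = n−1) form clusters by graph connectivity; cluster mass
    is the summed t; the null is the permutation distribution of the
    maximum cluster mass under random per-subject sign flips.  Cluster
    p-values use the add-one estimator (1 + #null ≥ mass) / (1 + n_perm).

    Returns (t_values, clusters, significance_mask).
    """
    n = stats.shape[0]
    if n < 2:
        raise ValueError("group inference needs at least 2 subjects")
    if n_perm < 100:
        log.warning("n_perm=%d is very low for cluster inference", n_perm)
    thr = student_t.ppf(1.0 - point_alpha, df=n - 1)
    sumsq = (stats ** 2).sum(axis=0)
    adjacency = sp.csr_matrix(adjacency)

    def _clusters(tv):
        supra = np.flatnonzero(tv >= thr)
        if supra.size == 0:
            return []
        sub = adjacency[supra][:, supra]
        n_comp, labels = connected_components(sub, directed=False)
        return [(supra[labels == k], float(tv[supra[labels == k]].sum()))
                for k in range(n_comp)]

    t_obs = _t_values(stats.mean(axis=0), sumsq, n)
    observed = _clusters(t_obs)

    rng = np.random.default_rng(seed)
    null = np.zeros(n_perm)
    for i in range(n_perm):
        signs = rng.choice(np.array([-1.0, 1.0]), size=n)
        mean_p = signs @ stats / n
        t_p = _t_values(mean_p, sumsq, n)
        comps = _clusters(t_p)
        if comps:
            null[i] = max(mass for _, mass in comps)

    clusters = []
    mask = np.zeros(stats.shape[1], dtype=bool)
    for points, mass in sorted(observed, key=lambda c: -c[1]):
        p = (1.0 + (null >= mass).sum()) / (1.0 + n_perm)
        clusters.append(Cluster(points=points, mass=mass, p=p))
        if p < cluster_alpha:
            mask[points] = True
    return t_obs, clusters, mask


def group_cluster_inference(fitmaps: list[FitMap], adjacency: sp.spmatrix,
                            point_alpha: float = 0.01,
                            cluster_alpha: float = 0.05,
                            n_perm: int = 5000, seed: int = 0) -> GroupResult:
    """Group-level cluster-permutation inference over subject fit maps.

    ``adjacency`` is the spatial vertex graph over the fit maps' vertices;
    temporal adjacency (consecutive centre times) is added internally, so
    clusters may span space and time jointly.  The test is one-tailed for
    positive mean model fit.
    """
    if len(fitmaps) < 2:
        raise ValueError("group inference needs at least 2 subjects")
    shapes = {fm.rho.shape for fm in fitmaps}
    if len(shapes) != 1:
        raise ValueError("fit maps have differing shapes")
    maps = np.stack([fm.rho for fm in fitmaps])
    n_subj, nv, nt = maps.shape
    finite = np.all(np.isfinite(maps), axis=0)
    flat_ok = np.flatnonzero(finite.ravel())

    adj_full = spatiotemporal_adjacency(sp.csr_matrix(adjacency), nt)
    adj = adj_full[flat_ok][:, flat_ok]
    stats = maps.reshape(n_subj, -1)[:, flat_ok]

    t_flat, clusters, mask_flat = cluster_sign_flip_test(
        stats, adj, point_alpha, cluster_alpha, n_perm, seed)

    t_map = np.full(nv * nt, np.nan)
    t_map[flat_ok] = t_flat
    mask = np.zeros(nv * nt, dtype=bool)
    mask[flat_ok] = mask_flat
    clusters = [Cluster(points=flat_ok[c.points], mass=c.mass, p=c.p)
                for c in clusters]
    fm0 = fitmaps[0]
    return GroupResult(t_map.reshape(nv, nt), mask.reshape(nv, nt), clusters,
                       np.asarray(fm0.vertices), fm0.center_times_ms,
                       fm0.model_label, point_alpha, cluster_alpha,
                       n_perm, seed)
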