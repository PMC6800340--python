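"""RDM-based lagged partial-correlation directed connectivity.

Granger-style logic on representational geometry: if region A drives
region B, then B's current data RDM D(B, t) should be explained by A's
earlier RDM D(A, t − dt) over and above B's own earlier RDM D(B, t − dt).
The directed connectivity A→B at (t, dt) is therefore the partial
(Spearman, by default) correlation between the condensed D(A, t − dt) and
D(B, t), partialling out D(B, t − dt).  Data RDMs here are *instantaneous*
(single-sample patterns over an ROI) to avoid contamination from
neighboring time points, and dt ranges over every sampling step from 2 ms
up to 120 ms by default.

Group inference mirrors the searchlight pipeline: per-subject maps over
the (t, dt) lattice are Fisher z-transformed, then a one-tailed sign-flip
cluster-mass permutation test with 4-neighborhood lattice adjacency is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
from scipy.stats import rankdata

from .rdm import RDM, UndefinedCorrelationError
from .ssrsa import (Cluster, GroupResult, SourceEpochs,
                    cluster_sign_flip_test, lattice_adjacency)

__all__ = [
    "RoiDefinition",
    "ConnectivityMap",
    "ConnectivityGroupResult",
    "default_lags_ms",
    "instantaneous_data_rdm",
    "directed_connectivity_map",
    "select_roi",
    "connectivity_cluster_inference",
]


@dataclass
class RoiDefinition:
    """A region of interest: vertex ids plus a record of how it was chosen."""

    vertices: np.ndarray
    source_label: str = ""
    n_top: int | None = None
    label_mask_id: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=int)
        if self.vertices.size == 0:
            raise ValueError("empty ROI")
        if self.n_top is not None and self.vertices.size > self.n_top:
            raise ValueError("ROI larger than its n_top selection rule")


@dataclass
class ConnectivityMap:
    """Partial-correlation map over (epoch time, lag) for an ordered pair.

    ``pcc[t, k]`` is defined only when t − lags[k] is inside the epoch;
    undefined points are NaN.
    """

    pcc: np.ndarray             # (n_times, n_lags)
    times_ms: np.ndarray
    lags_ms: np.ndarray
    direction: tuple[str, str]  # (source, target)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.pcc = np.asarray(self.pcc, dtype=float)
        self.lags_ms = np.asarray(self.lags_ms, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.pcc.shape != (self.times_ms.size, self.lags_ms.size):
            raise ValueError("pcc shape does not match time/lag grids")
        if (np.diff(self.lags_ms) <= 0).any() or (self.lags_ms <= 0).any():
            raise ValueError("lag grid must be strictly increasing and positive")


def save_connectivity_stack(path, maps: list[ConnectivityMap],
                            mask: np.ndarray | None = None) -> None:
    m0 = maps[0]
    with h5py.File(path, "w") as f:
        f.create_dataset("pcc", data=np.stack([m.pcc for m in maps]))
        f.create_dataset("times_ms", data=m0.times_ms)
        f.create_dataset("lags_ms", data=m0.lags_ms)
        f.create_dataset("subject_ids",
                         data=np.array([m.subject_id for m in maps],
                                       dtype=object),
                         dtype=h5py.string_dtype())
        if mask is not None:
            f.create_dataset("mask", data=mask.astype(np.uint8))
        f.attrs["source"] = m0.direction[0]
        f.attrs["target"] = m0.direction[1]


@dataclass
class ConnectivityGroupResult:
    """Cluster-permutation result over the (time, lag) lattice."""

    t_map: np.ndarray
    mask: np.ndarray
    clusters: list[Cluster]
    times_ms: np.ndarray
    lags_ms: np.ndarray
    direction: tuple[str, str]
    point_alpha: float
    cluster_alpha: float
    n_perm: int
    seed: int

    def cluster_table(self):
        import pandas as pd
        return pd.DataFrame(
            [{"cluster": i, "n_points": len(c.points), "mass": c.mass, "p": c.p}
             for i, c in enumerate(self.clusters)],
            columns=["cluster", "n_points", "mass", "p"])


def default_lags_ms(step_ms: float, lo_ms: float = 2.0,
                    hi_ms: float = 120.0) -> np.ndarray:
    """Every sampling step from ``lo_ms`` to ``hi_ms`` inclusive."""
    return np.arange(max(step_ms, lo_ms), hi_ms + step_ms / 2, step_ms)


def instantaneous_data_rdm(epochs: SourceEpochs, roi: RoiDefinition | np.ndarray,
                           time_ms: float) -> RDM:
    """Correlation-distance RDM from single-sample ROI patterns."""
    verts = roi.vertices if isinstance(roi, RoiDefinition) else np.asarray(roi, int)
    if verts.size < 2:
        raise ValueError("instantaneous RDM needs an ROI with >= 2 vertices")
    t = epochs.time_index(time_ms)
    feats = np.asarray(epochs.data[:, verts, t], dtype=float)
    sd = feats.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise UndefinedCorrelationError(
            f"constant pattern for trial {epochs.trial_ids[bad[0]]!r}")
    D = 1.0 - np.corrcoef(feats)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return RDM(D, list(epochs.trial_ids), "data", "correlation_distance")


def _condensed_rank_series(epochs: SourceEpochs, verts: np.ndarray,
                           rank: bool) -> np.ndarray:
    """Standardized (ranked) condensed instantaneous RDMs, one row per sample.

    Rows are demeaned and scaled to unit norm so that dot products between
    rows of two series are (Spearman or Pearson) correlations.
    """
    Y = np.asarray(epochs.data[:, verts, :], dtype=float)   # n, m, T
    Z = Y.transpose(2, 0, 1)                                 # T, n, m
    Z = Z - Z.mean(axis=2, keepdims=True)
    norms = np.linalg.norm(Z, axis=2)
    if (norms == 0).any():
        t_bad, i_bad = np.argwhere(norms == 0)[0]
        raise UndefinedCorrelationError(
            f"constant pattern for trial {epochs.trial_ids[i_bad]!r} "
            f"at {epochs.times_ms[t_bad]} ms")
    G = Z @ Z.transpose(0, 2, 1)
    R = G / (norms[:, :, None] * norms[:, None, :])
    n = epochs.n_trials
    iu = np.triu_indices(n, k=1)
    cond = 1.0 - R[:, iu[0], iu[1]]                          # T, L
    if rank:
        cond = rankdata(cond, axis=1)
    cond = cond - cond.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(cond, axis=1, keepdims=True)
    if (norms == 0).any():
        raise UndefinedCorrelationError("constant condensed data RDM")
    return cond / norms


def directed_connectivity_map(epochs: SourceEpochs,
                              roi_a: RoiDefinition | np.ndarray,
                              roi_b: RoiDefinition | np.ndarray,
                              lags_ms: np.ndarray | None = None,
                              method: str = "spearman",
                              names: tuple[str, str] = ("A", "B"),
                              ) -> ConnectivityMap:
    """Directed connectivity A→B over the (epoch time, lag) grid.

    pcc(t, dt) = partial correlation between D(A, t − dt) and D(B, t),
    partialling out D(B, t − dt), on condensed instantaneous data RDMs.
    Rank-based by default (``method='spearman'``); ``'pearson'`` operates
    on raw condensed distances.  Points with t − dt before epoch start are
    NaN.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    step = epochs.step_ms
    if lags_ms is None:
        lags_ms = default_lags_ms(step)
    lags_ms = np.asarray(lags_ms, dtype=float)
    lag_steps = lags_ms / step
    if np.abs(lag_steps - np.round(lag_steps)).max() > 1e-9 or \
            (lags_ms <= 0).any():
        raise ValueError("lags must be positive multiples of the sampling step")
    lag_steps = np.round(lag_steps).astype(int)

    va = roi_a.vertices if isinstance(roi_a, RoiDefinition) else np.asarray(roi_a, int)
    vb = roi_b.vertices if isinstance(roi_b, RoiDefinition) else np.asarray(roi_b, int)
    rank = method == "spearman"
    RA = _condensed_rank_series(epochs, va, rank)
    RB = _condensed_rank_series(epochs, vb, rank)

    C_ab = RA @ RB.T          # corr(A at row, B at col)
    C_bb = RB @ RB.T
    T = epochs.n_samples
    pcc = np.full((T, lag_steps.size), np.nan)
    tgrid = np.arange(T)
    for k, d in enumerate(lag_steps):
        ts = tgrid[tgrid - d >= 0]
        prev = ts - d
        r_xy = C_ab[prev, ts]         # corr(A[t-d], B[t])
        r_xz = C_ab[prev, prev]       # corr(A[t-d], B[t-d])
        r_yz = C_bb[ts, prev]         # corr(B[t],  B[t-d])
        denom = (1.0 - r_xz ** 2) * (1.0 - r_yz ** 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            val = (r_xy - r_xz * r_yz) / np.sqrt(denom)
        val[denom <= 0] = np.nan
        pcc[ts, k] = val
    return ConnectivityMap(pcc, epochs.times_ms.copy(), lags_ms,
                           direction=names, subject_id=epochs.subject_id)


def select_roi(group: GroupResult, label_mask, n_top: int = 100,
               label_mask_id: str = "") -> RoiDefinition:
    """Select the most significant vertices of a group result within a mask.

    Each vertex is scored by the sum of its t values over significant
    (cluster-masked) time points; the top ``n_top`` scoring vertices within
    ``label_mask`` are returned, ties broken by ascending vertex id.
    """
    label_mask = np.asarray(label_mask, dtype=int)
    rows = {v: i for i, v in enumerate(np.asarray(group.vertices))}
    cand = np.array([v for v in label_mask if v in rows], dtype=int)
    if cand.size == 0:
        raise ValueError("label mask does not intersect the group result")
    t_map = np.where(group.mask, np.nan_to_num(group.t_map), 0.0)
    scores = np.array([t_map[rows[v]].sum() for v in cand])
    if not (scores > 0).any():
        raise ValueError("significance mask does not intersect the label mask")
    order = np.lexsort((cand, -scores))
    chosen = np.sort(cand[order[:n_top]])
    return RoiDefinition(chosen, source_label=group.model_label,
                         n_top=n_top, label_mask_id=label_mask_id)


def connectivity_cluster_inference(maps: list[ConnectivityMap],
                                   point_alpha: float = 0.001,
                                   cluster_alpha: float = 0.01,
                                   n_perm: int = 5000, seed: int = 0,
                                   fisher: bool = True,
                                   ) -> ConnectivityGroupResult:
    """Group cluster-permutation inference on (time, lag) connectivity maps.

    Per-subject pcc values are Fisher z-transformed (variance
    stabilization) before the one-tailed sign-flip cluster-mass test;
    adjacency is the 4-neighborhood of the (t, dt) lattice; NaN points
    (t − dt before epoch start) are excluded from clustering.
    """
    if len(maps) < 2:
        raise ValueError("group inference needs at least 2 subjects")
    shapes = {m.pcc.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError("connectivity maps have differing grids")
    stack = np.stack([m.pcc for m in maps])
    n_subj, nt, nl = stack.shape
    if fisher:
        stack = np.arctanh(np.clip(stack, -1 + 1e-12, 1 - 1e-12))
    finite = np.all(np.isfinite(stack), axis=0)
    flat_ok = np.flatnonzero(finite.ravel())
    adj = lattice_adjacency((nt, nl))[flat_ok][:, flat_ok]
    stats = stack.reshape(n_subj, -1)[:, flat_ok]

    t_flat, clusters, mask_flat = cluster_sign_flip_test(
        stats, adj, point_alpha, cluster_alpha, n_perm, seed)

    t_map = np.full(nt * nl, np.nan)
    t_map[flat_ok] = t_flat
    mask = np.zeros(nt * nl, dtype=bool)
    mask[flat_ok] = mask_flat
    clusters = [Cluster(points=flat_ok[c.points], mass=c.mass, p=c.p)
                for c in clusters]
    m0 = maps[0]
    return ConnectivityGroupResult(t_map.reshape(nt, nl),
                                   mask.reshape(nt, nl), clusters,
                                   m0.times_ms, m0.lags_ms, m0.direction,
                                   point_alpha, cluster_alpha, n_perm, seed)
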