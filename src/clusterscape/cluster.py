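"""Density-based clustering of 3-D embeddings with deterministic labeling.

DBSCAN with the classical semantics — a core point has at least ``min_pts``
neighbors within ``eps`` (itself included), clusters are connected
components of core points plus the border points they reach, everything
else is noise (label -1) — but with both of DBSCAN's order ambiguities
pinned down:

* a border point reachable from several clusters joins the cluster whose
  formation starts earliest under an ascending-id scan, and
* final cluster numbers 0..k-1 are assigned by decreasing cluster size,
  ties broken by the lexicographically smallest member id.

The result is therefore invariant under permutation of the input points,
which off-the-shelf DBSCAN implementations do not guarantee for border
points.  Defaults eps = 2 and min_pts = 10 suit t-SNE embeddings whose
coordinates span roughly [-20, 20].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.neighbors import NearestNeighbors

from .io import PointCloud

__all__ = ["DbscanParams", "ClusterLabels", "DeterministicDBSCAN", "cluster_dbscan"]

NOISE = -1


@dataclass
class DbscanParams:
    eps: float = 2.0
    min_pts: int = 10

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.min_pts < 1:
            raise ValueError("min_pts must be at least 1")


@dataclass
class ClusterLabels:
    """Integer cluster assignment per id; -1 marks noise, clusters are 0..k-1."""

    ids: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.ids) != len(self.labels):
            raise ValueError("ids and labels must have equal length")
        clusters = sorted(set(self.labels.tolist()) - {NOISE})
        if clusters != list(range(len(clusters))):
            raise ValueError("cluster labels must be exactly 0..k-1 (plus -1 for noise)")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max() + 1) if (self.labels >= 0).any() else 0

    @property
    def n_noise(self) -> int:
        return int((self.labels == NOISE).sum())

    def to_dict(self) -> dict:
        return dict(zip(self.ids.tolist(), self.labels.tolist()))

    def to_csv(self, path) -> None:
        pd.DataFrame({"id": self.ids, "cluster": self.labels}).to_csv(
            path, index=False, encoding="utf-8"
        )

    @classmethod
    def from_csv(cls, path) -> "ClusterLabels":
        frame = pd.read_csv(Path(path), dtype={"id": str, "cluster": int}, encoding="utf-8")
        return cls(ids=frame["id"].to_numpy(dtype=object), labels=frame["cluster"].to_numpy())


def _renumber(labels: np.ndarray, ids: np.ndarray) -> np.ndarray:
    """Renumber clusters 0..k-1 by decreasing size; ties by smallest member id."""
    out = np.full(len(labels), NOISE, dtype=int)
    clusters = sorted(set(labels.tolist()) - {NOISE})
    keyed = []
    for c in clusters:
        members = labels == c
        keyed.append((-int(members.sum()), min(map(str, ids[members])), c))
    for new, (_, _, old) in enumerate(sorted(keyed)):
        out[labels == old] = new
    return out


class DeterministicDBSCAN(BaseEstimator, ClusterMixin):
    """DBSCAN with order-independent border assignment and cluster numbering.

    Parameters
    ----------
    eps : float, default 2.0
        Neighborhood radius (closed ball: distance <= eps).
    min_samples : int, default 10
        Neighbors (self included) required for a core point.

    Attributes
    ----------
    labels_ : ndarray of int
        Cluster label per sample; -1 is noise.
    core_sample_indices_ : ndarray of int
    n_clusters_ : int
    """

    def __init__(self, eps: float = 2.0, min_samples: int = 10):
        self.eps = eps
        self.min_samples = min_samples

    def fit(self, X, y=None, ids=None):
        DbscanParams(eps=self.eps, min_pts=self.min_samples)  # validates
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D coordinate array")
        if not np.all(np.isfinite(X)):
            raise ValueError("coordinates must be finite")
        n = X.shape[0]
        if ids is None:
            ids = np.array([f"p{i}" for i in range(n)], dtype=object)
        ids = np.asarray(ids, dtype=object)

        if n == 0:
            self.labels_ = np.empty(0, dtype=int)
            self.core_sample_indices_ = np.empty(0, dtype=int)
            self.n_clusters_ = 0
            return self

        nn = NearestNeighbors(radius=self.eps).fit(X)
        # explicit query matrix => each point appears as its own neighbor,
        # so row degree is already the count-with-self DBSCAN needs
        graph = nn.radius_neighbors_graph(X, mode="connectivity")
        degree = np.asarray(graph.sum(axis=1)).ravel()
        core = degree >= self.min_samples

        labels = np.full(n, NOISE, dtype=int)
        n_comp = 0
        if core.any():
            core_idx = np.flatnonzero(core)
            core_graph = graph[np.ix_(core_idx, core_idx)]
            n_comp, comp = connected_components(core_graph, directed=False)
            labels[core_idx] = comp

            # provisional numbering = formation order in an ascending-id scan:
            # the component containing the smallest-id core point forms first
            first_id = {}
            for pos, i in enumerate(core_idx):
                c = comp[pos]
                key = str(ids[i])
                if c not in first_id or key < first_id[c]:
                    first_id[c] = key
            order = {c: r for r, (_, c) in enumerate(sorted((v, k) for k, v in first_id.items()))}
            labels[core_idx] = [order[c] for c in comp]

            # border points join the earliest-formed cluster among their core neighbors
            border = np.flatnonzero(~core)
            indptr, indices = graph.indptr, graph.indices
            for b in border:
                neigh = indices[indptr[b] : indptr[b + 1]]
                neigh_clusters = labels[neigh[core[neigh]]]
                if neigh_clusters.size:
                    labels[b] = int(neigh_clusters.min())

        self.labels_ = _renumber(labels, ids)
        self.core_sample_indices_ = np.flatnonzero(core)
        self.n_clusters_ = n_comp
        return self

    def fit_predict(self, X, y=None, ids=None) -> np.ndarray:
        return self.fit(X, ids=ids).labels_


def cluster_dbscan(cloud: PointCloud, params: DbscanParams | None = None) -> ClusterLabels:
    """Cluster a 3-D point cloud with deterministic DBSCAN (defaults eps=2, min_pts=10)."""
    params = params or DbscanParams()
    if cloud.dims != 3:
        raise ValueError("cluster_dbscan expects 3D coordinates; apply lift_to_3d first")
    est = DeterministicDBSCAN(eps=params.eps, min_samples=params.min_pts)
    est.fit(cloud.coords, ids=cloud.ids)
    return ClusterLabels(ids=cloud.ids.copy(), labels=est.labels_)
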